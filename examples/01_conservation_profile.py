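"""Conservation profile of a synthetic lobe alignment.

Simulates a 40-column alignment with three perfectly conserved columns in a
diverged background, computes the per-column normalised BLOSUM (NBS)
profile, and prints the summary statistics and the most conserved columns.
"""

import numpy as np

from tbpsig import AlignmentSpec, profile_stats, simulate_alignment

planted = [5, 17, 30]
theta = np.where(np.isin(np.arange(40), planted), 0.0, 0.7)
aln = simulate_alignment(
    AlignmentSpec(n_seqs={"eukaryote": 40}, n_columns=40, theta=theta, seed=7)
)

profile = profile_stats(aln)
print(f"{len(aln)} sequences x {aln.n_columns} columns")
print(f"mean NBS = {profile.mean_nbs:.3f}, SD = {profile.sd_nbs:.3f} "
      f"over {profile.n_scorable} scorable columns")

order = np.argsort(-np.nan_to_num(profile.per_column, nan=-2))
print("top-5 columns by NBS (1-based):")
for j in order[:5]:
    print(f"  column {j + 1:3d}  NBS = {profile.per_column[j]:+.3f}")

# NBS is the mean normalised substitution score over all sequence pairs at a
# column: +1 means every pair identical, values near the background mean
# (~ -0.1 for diverged columns) mean no conservation. The three planted
# columns surface at NBS = 1.
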