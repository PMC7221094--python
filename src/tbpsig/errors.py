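"""Exception hierarchy.

Every error raised by the library derives from :class:`TbpsigError` so callers
can catch the package's failures without trapping programming errors.
"""


class TbpsigError(Exception):
    """Base class for all tbpsig errors."""


class EmptyInputError(TbpsigError):
    """An input file or collection contained no usable records."""


class AlignmentShapeError(TbpsigError):
    """Sequences of unequal length, or a sequence of the wrong length."""


class AlphabetError(TbpsigError):
    """A residue character outside the declared alphabet."""


class EmptySelectionError(TbpsigError):
    """A subset filter matched no sequences."""


class GrammarError(TbpsigError):
    """A position label that does not follow the dotted grammar."""


class TemplateOverflowError(TbpsigError):
    """A secondary-structure template longer than the alignment."""


class InsufficientDepthError(TbpsigError):
    """A column with fewer than two sequences."""


class DegenerateProfileError(TbpsigError):
    """A conservation profile with zero scorable columns."""


class ContextError(TbpsigError):
    """Wrong number of ancestral sequences for the universal-signature test."""


class InsufficientPairsError(TbpsigError):
    """Fewer than three organism-matched sequence pairs."""


class UndefinedCorrelationError(TbpsigError):
    """Pearson correlation undefined (zero variance or too few entries)."""


class TargetColumnError(TbpsigError):
    """The scan's target column is unscorable."""


class ParameterError(TbpsigError):
    """Inconsistent or out-of-range parameters."""


class SchemaError(TbpsigError):
    """A tabular input missing required columns."""


class RowError(TbpsigError):
    """A malformed row in a tabular input; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class MappingMismatchError(TbpsigError):
    """Structure sequence does not match the aligned row it is mapped to."""


class UndefinedMDRError(TbpsigError):
    """Mutation-density ratio requested but one variant source is entirely absent."""


class ConfigError(TbpsigError):
    """Invalid or incomplete run configuration."""
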