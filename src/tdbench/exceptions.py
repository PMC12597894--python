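"""Exception hierarchy.

Everything derives from :class:`TDBenchError` so callers can catch the
package's failures with one clause; subclasses additionally derive from the
closest builtin (``ValueError`` for bad inputs) so generic handling works too.
"""


class TDBenchError(Exception):
    """Base class for all errors raised by tdbench."""


class ConfigError(TDBenchError, ValueError):
    """A configuration value (column map, preset name, grid, ...) is invalid."""


class ParseError(TDBenchError, ValueError):
    """A cell of an input table could not be parsed; carries coordinates."""


class EmptyInputError(TDBenchError, ValueError):
    """An input file or container holds zero data rows."""


class InvalidTableError(TDBenchError, ValueError):
    """A score table violates an invariant (e.g. no targets or no decoys)."""


class UnsupportedResidueError(TDBenchError, ValueError):
    """A peptide contains a letter outside the 20 standard amino acids."""


class SequenceLengthError(TDBenchError, ValueError):
    """A peptide is too short for the decoy mutation scheme."""


class DegenerateTrainingError(TDBenchError, ValueError):
    """Training labels contain a single class."""


class InsufficientDataError(TDBenchError, ValueError):
    """Fewer rows than a classifier can be fitted on."""


class ShapeError(TDBenchError, ValueError):
    """Feature count of scoring input does not match the fitted model."""


class InitializationError(TDBenchError, RuntimeError):
    """No single sub-score column selects any target at the initial q cut."""


class CollapseError(TDBenchError, RuntimeError):
    """The semi-supervised positive set became empty.

    Attributes
    ----------
    iteration : int
        Zero-based index of the iteration at which the collapse occurred.
    """

    def __init__(self, iteration: int, message: str | None = None):
        self.iteration = iteration
        super().__init__(
            message
            or f"semi-supervised positive set is empty at iteration {iteration}; "
            "consider a larger q_learn"
        )


class StratificationError(TDBenchError, ValueError):
    """A cross-validation fold lost one of the two classes; use fewer folds."""


class EstimatorUndefinedError(TDBenchError, ValueError):
    """Decoy-based FDR requested without any decoy rows."""


class UndefinedMetricError(TDBenchError, ValueError):
    """Entrapment-based metric requested on a table without entrapment rows."""


class ContractError(TDBenchError, ValueError):
    """An operation received rows that its contract forbids (e.g. decoys)."""
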