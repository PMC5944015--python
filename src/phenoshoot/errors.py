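"""Exception hierarchy.

All errors derive from :class:`PhenoshootError` so callers can catch the
package's failures with one clause; most also derive from the matching
builtin (``ValueError`` / ``RuntimeError``) so generic handling works too.
"""


class PhenoshootError(Exception):
    """Base class for all phenoshoot errors."""


class InvalidArgumentError(PhenoshootError, ValueError):
    """An argument violates a documented precondition."""


class EmptyInputError(PhenoshootError, ValueError):
    """An operation received an empty mask / table where content is required."""


class RegistrationError(PhenoshootError, RuntimeError):
    """Feature-based image registration could not find enough reliable matches."""


class UnsupportedTopologyError(PhenoshootError, RuntimeError):
    """The skeleton graph contains cycles (leaf crossover / self-occlusion)."""


class SchemaError(PhenoshootError, ValueError):
    """A ground-truth XML document does not conform to the expected schema."""


class InsufficientPointsError(PhenoshootError, ValueError):
    """Too few points for a curve fit."""


class DegenerateLeafError(PhenoshootError, ValueError):
    """Leaf geometry is degenerate (coincident junction/tip abscissae)."""


class UndefinedChordError(PhenoshootError, ValueError):
    """Junction and tip coincide; the junction-tip chord is undefined."""


class InsufficientJunctionsError(PhenoshootError, ValueError):
    """Fewer than two junctions; the stem axis cannot be regressed."""


class UndefinedFrameError(PhenoshootError, ValueError):
    """A frame with zero ground-truth leaves makes the accuracy undefined."""


class AliasedEffectsError(PhenoshootError, ValueError):
    """The effects-model design matrix is rank deficient beyond reference coding."""
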