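"""Exception hierarchy for nichehybrid."""


class NicheHybridError(Exception):
    """Base class for all package-specific errors."""


class EmptyInputError(NicheHybridError, ValueError):
    """An input file or collection that must be non-empty is empty."""


class AlignmentLengthError(NicheHybridError, ValueError):
    """Sequences in an alignment do not all share the same length."""


class AlphabetError(NicheHybridError, ValueError):
    """A sequence contains a character outside {A, C, G, T, -, N}."""


class DuplicateIdError(NicheHybridError, ValueError):
    """An identifier that must be unique occurs more than once."""


class MissingAbundanceError(NicheHybridError, ValueError):
    """An OTU present in the alignment has no abundance record."""


class DegeneratePartitionError(NicheHybridError, ValueError):
    """The modal/rare split left one side empty, so no distance sample exists."""


class InsufficientDataError(NicheHybridError, ValueError):
    """Too few observations (or zero spread) to run the requested analysis."""


class DegenerateSampleError(NicheHybridError, ValueError):
    """A sample with zero variance cannot be smooth-bootstrapped."""


class GenerationError(NicheHybridError, RuntimeError):
    """The synthetic-community generator could not satisfy its constraints."""


class ConvergenceError(NicheHybridError, RuntimeError):
    """An iterative numeric search failed to converge within its cap."""
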