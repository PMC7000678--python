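"""Exception hierarchy shared across the pipeline stages."""


class NeustonError(Exception):
    """Base class for all package-specific errors."""


class DuplicateIdError(NeustonError):
    """Two records in one input share a sequence id."""


class AlphabetError(NeustonError):
    """A residue outside the accepted nucleotide alphabet was read."""


class EmptyInputError(NeustonError):
    """An input file contained no records."""


class MissingGroupError(NeustonError):
    """A sequence id has no entry in the group map."""


class DegenerateAlignmentError(NeustonError):
    """Complete deletion removed every alignment column."""


class InsufficientSampleError(NeustonError):
    """A diversity statistic was requested for fewer than two sequences."""


class DisjointnessError(NeustonError):
    """Two clade subsets that must be disjoint overlap."""


class GapError(NeustonError):
    """Gap characters present where a dealigned sequence is required."""


class ConfigError(NeustonError):
    """Invalid simulation or pipeline configuration."""


class NonConvergenceError(NeustonError):
    """Median-joining node growth exceeded its ceiling.

    Carries the partial network in ``partial``.
    """

    def __init__(self, message, partial=None):
        super().__init__(message)
        self.partial = partial
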