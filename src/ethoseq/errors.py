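"""Exception hierarchy."""


class EthoseqError(Exception):
    """Base class for all ethoseq errors."""


class UnknownBehaviorCode(EthoseqError):
    """An ethogram file contains a label outside the 12-code vocabulary."""


class NonContiguousFrames(EthoseqError):
    """Frame indices are not 0,1,2,... without gaps."""


class EmptyFile(EthoseqError):
    """An ethogram file has no data rows."""


class DegenerateSubsequence(EthoseqError):
    """A subsequence contains only instantaneous (strike) frames."""


class InvalidFeedState(EthoseqError):
    """Feed state outside 0..4."""


class InsufficientData(EthoseqError):
    """Too few observations for the requested statistic."""


class LengthMismatch(EthoseqError):
    """Vectors of unequal length passed to a distance."""


class WrongLength(EthoseqError):
    """A feature vector of the wrong size passed to unvectorize."""


class InvalidDecimation(EthoseqError):
    """Decimation window k must be >= 1."""
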