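"""Exception types shared across the package."""


class TwoChainError(Exception):
    """Base class for package-specific failures."""


class ValidationError(TwoChainError):
    """A file or data structure violates its contract."""


class StitchingError(TwoChainError):
    """Adjacent umbrella windows do not overlap; the PMF cannot be stitched."""


class TailAnchorError(TwoChainError):
    """A PMF is not anchored to zero at large separations."""


class BracketError(TwoChainError):
    """An epsilon bracket does not straddle the target B22."""


class SamplingShortfallError(TwoChainError):
    """Fewer decorrelated well configurations are available than requested."""

    def __init__(self, requested: int, achievable: int):
        self.requested = requested
        self.achievable = achievable
        super().__init__(
            f"requested {requested} decorrelated well configurations, "
            f"only {achievable} available"
        )


class DegenerateSpectrumError(TwoChainError):
    """A power spectrum with zero total power has no explained-variance curves."""


class UndefinedAUCError(TwoChainError):
    """ROC-AUC is undefined when only one class is present."""


class ClassImbalanceError(TwoChainError):
    """Could not draw a train/test split containing both classes."""
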