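"""Exception hierarchy shared across the package."""


class InvriskError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(InvriskError):
    """Raised when input records or files violate the census schema."""


class PhyloError(InvriskError):
    """Raised for phylogeny problems: bad Newick, unknown tips, bad traits."""


class FitError(InvriskError):
    """Raised when a logistic fit cannot be produced (rank deficiency,
    degenerate response, non-convergence)."""


class AvailabilityError(InvriskError):
    """Raised when no submodel yields a prediction for a pair."""
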