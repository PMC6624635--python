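"""Exception hierarchy for the gland-segmentation pipeline.

Errors are split into two families so the CLI can map them onto exit
codes: :class:`InvalidInputError` (caller gave us something malformed,
exit code 2) and :class:`DegenerateDataError` (the data itself cannot
support the requested computation, exit code 3).
"""


class GlandSegError(Exception):
    """Base class for all package errors."""


class InvalidInputError(GlandSegError):
    """Malformed input: wrong shape, non-RGB image, bad parameter value."""


class InvalidConfigError(InvalidInputError):
    """A configuration value is out of its valid range."""


class InvalidSeedError(InvalidInputError):
    """A watershed seed lies outside the segmentation mask."""

    def __init__(self, seed_id: int):
        self.seed_id = seed_id
        super().__init__(f"seed {seed_id} lies outside the segmentation mask")


class DegenerateDataError(GlandSegError):
    """The data cannot support the computation (e.g. an all-white tile)."""


class DegenerateInputError(DegenerateDataError):
    """Input carries no usable signal (constant map, empty cloud)."""


class DegenerateStainError(DegenerateDataError):
    """Stain model is unusable: collapsed or collinear reference colors."""


class DegenerateClusterError(DegenerateDataError):
    """Cluster statistics are singular (e.g. singular pooled covariance)."""


class ConvergenceError(GlandSegError):
    """Iterative fit failed to converge; carries the iteration count."""

    def __init__(self, message: str, n_iter: int):
        self.n_iter = n_iter
        super().__init__(f"{message} (after {n_iter} iterations)")
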