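"""Exception hierarchy shared across the package."""


class LarimorphError(Exception):
    """Base class for all package-specific errors."""


class InvalidMeasurementError(LarimorphError, ValueError):
    """A raw measurement violates its physical constraints (e.g. non-positive mass)."""


class DegenerateInputError(LarimorphError, ValueError):
    """Input is formally valid but carries no usable signal (e.g. constant vector)."""


class NewickParseError(LarimorphError, ValueError):
    """Malformed Newick text or missing branch lengths."""


class TreeError(LarimorphError, ValueError):
    """A tree operation received an invalid tree or label set."""


class NameMatchError(TreeError):
    """Species names in a table could not be matched to tree tips."""

    def __init__(self, missing_in_tree=(), missing_in_table=()):
        self.missing_in_tree = sorted(missing_in_tree)
        self.missing_in_table = sorted(missing_in_table)
        parts = []
        if self.missing_in_tree:
            parts.append(f"names absent from tree: {', '.join(self.missing_in_tree)}")
        if self.missing_in_table:
            parts.append(f"tips absent from table: {', '.join(self.missing_in_table)}")
        super().__init__("; ".join(parts) or "name mismatch")


class ConvergenceError(LarimorphError, RuntimeError):
    """An iterative fit failed to converge; the message carries the trace."""


class CholeskyError(LarimorphError, ValueError):
    """A covariance structure was not positive definite."""
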