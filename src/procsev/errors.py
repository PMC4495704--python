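"""Exception types shared across the package."""


class ProcsevError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ProcsevError):
    """A required column is missing or the column mapping is inconsistent."""


class CohortLoadError(ProcsevError):
    """One or more rows of an input file could not be parsed.

    Attributes
    ----------
    row_errors : list of (line_number, message)
    """

    def __init__(self, row_errors):
        self.row_errors = list(row_errors)
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in self.row_errors)
        super().__init__(f"{len(self.row_errors)} malformed row(s): {lines}")


class ConfigError(ProcsevError):
    """Invalid user configuration (catalogs, group policies, weights...)."""


class ZeroMarginError(ProcsevError):
    """A 2x2 table has an empty row or column margin; the statistic is undefined."""


class SingularDesignError(ProcsevError):
    """The regression design matrix is rank deficient."""

    def __init__(self, aliased):
        self.aliased = list(aliased)
        super().__init__(
            "singular design matrix; aliased terms: " + ", ".join(self.aliased)
        )


class ConvergenceError(ProcsevError):
    """The likelihood maximisation did not converge (possible separation)."""


class NoReferenceError(ProcsevError):
    """Neither CCI level provides a usable reference coefficient."""
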