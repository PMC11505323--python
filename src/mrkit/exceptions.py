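"""Exception hierarchy.

Everything raised deliberately by mrkit derives from :class:`MRKitError`
so callers can catch package failures without masking programming errors.
"""


class MRKitError(Exception):
    """Base class for all mrkit errors."""


class ColumnMapError(MRKitError, KeyError):
    """A mapped column is missing from an input summary-statistics table."""


class EmptyInputError(MRKitError, ValueError):
    """An operation received (or produced) zero usable rows."""


class MethodMinimumError(MRKitError, ValueError):
    """Too few instruments for the requested estimator.

    Each estimator has a hard minimum: Wald ratio 1, IVW 2, Egger 3,
    median/mode estimators 3, MVMR k+2 for k exposures, MR-PRESSO 4.
    """


class UndefinedRatioError(MRKitError, ZeroDivisionError):
    """Wald ratio requested for a SNP with zero exposure effect."""


class CollinearityError(MRKitError, ValueError):
    """Rank-deficient exposure matrix in multivariable MR."""


class LDTableError(MRKitError, ValueError):
    """Malformed (e.g. asymmetric) pairwise-r2 table."""
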