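"""Exception types raised by collapsemask."""


class CollapsemaskError(Exception):
    """Base class for all package-specific errors."""


class VcfFormatError(CollapsemaskError):
    """Malformed or unusable VCF input (missing fields, bad records)."""


class FilterError(CollapsemaskError):
    """No usable data survives filtering."""


class DataError(CollapsemaskError):
    """Input data violates a precondition (too few SNPs, mismatched sets...)."""


class FitError(CollapsemaskError):
    """A model fit produced non-finite or invalid results."""
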