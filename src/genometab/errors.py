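"""Exception hierarchy shared by all genometab modules."""


class GenometabError(Exception):
    """Base class for all package errors."""


class ValidationError(GenometabError, ValueError):
    """A spec object or argument violates its invariants."""


class AlignmentError(GenometabError, ValueError):
    """Tables that must share subjects do not line up."""


class SchemaError(GenometabError, ValueError):
    """An input file is missing required columns or contains bad values."""


class ReferencingError(GenometabError, ValueError):
    """No usable reference peak found when aligning a spectrum."""


class CoverageError(GenometabError, ValueError):
    """A spectrum does not cover the requested analysis window."""


class NormalizationError(GenometabError, ValueError):
    """Total spectral area is zero or negative; cannot normalize."""
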