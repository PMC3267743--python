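"""Exception hierarchy.

All domain errors derive from :class:`CtNormError` so callers (and the CLI)
can distinguish usage problems from data problems with a single except clause.
"""


class CtNormError(Exception):
    """Base class for all ctnorm domain errors."""


class ParseError(CtNormError):
    """A cell could not be interpreted as a Ct value or a non-detection token."""


class DuplicateLabelError(CtNormError):
    """A gene or sample identifier occurs more than once."""


class SchemaError(CtNormError):
    """A required column is missing from an input table."""


class NoFullyDetectedGenesError(CtNormError):
    """No gene is detected in every sample at the requested Ct threshold.

    The standard remedies are raising the detection threshold (useful when
    some samples are RNA-depleted) or removing outlier samples with very
    little amplifiable RNA.
    """


class DegenerateScaleError(CtNormError):
    """A sample has zero median absolute deviation; scale normalization is undefined."""


class DegenerateInputError(CtNormError):
    """Input vectors are constant and identical; concordance is undefined."""
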