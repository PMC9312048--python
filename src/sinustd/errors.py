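"""Exception hierarchy for sinustd.

The CLI maps these onto exit codes: format/data problems (3) and
geometry/eligibility problems (4); anything else is a usage error (2).
"""


class SinusTDError(Exception):
    """Base class for all sinustd errors."""


class ConfigurationError(SinusTDError):
    """Invalid configuration, e.g. a ray fan outside the open interval (0, 180) degrees."""


class GeometryError(SinusTDError):
    """Geometric failure: degenerate baseline, origin off the baseline, a ray that misses the outline."""


class EligibilityError(GeometryError):
    """Outline violates the eligibility rules required before profile measurement."""


class FormatError(SinusTDError):
    """Malformed or inconsistent input data (files, exports, masks)."""


class ComparisonError(SinusTDError):
    """Profiles cannot be compared (mismatched angle sets or lengths)."""


class DesignError(SinusTDError):
    """A statistical design requirement is violated (incomplete or unbalanced repeated measures)."""
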