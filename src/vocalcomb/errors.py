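"""Exception hierarchy shared across the package."""


class VocalcombError(Exception):
    """Base class for all package errors."""


class FormatError(VocalcombError):
    """Malformed file content (e.g. a TextGrid interval with end <= start)."""


class HierarchyError(VocalcombError):
    """The segment/call/combination nesting structure is violated or missing."""


class LabelError(VocalcombError):
    """A label is outside the expected alphabet."""


class OrderingError(VocalcombError):
    """Units expected sorted and non-overlapping are not."""


class ConfigError(VocalcombError):
    """Invalid configuration (band edges, output sizes, parameter ranges)."""


class ParameterError(VocalcombError):
    """Invalid run-time parameter (e.g. n_perm < 1, too few rows)."""


class DegenerateUnitError(VocalcombError):
    """A vocal unit too short to analyse (shorter than one analysis window)."""


class SpecError(VocalcombError):
    """A synthetic-generator specification that cannot be realized."""
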