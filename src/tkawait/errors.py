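"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration file is missing required keys or is unreadable."""


class ValidationError(ValueError):
    """A parameter or table value violates its documented bounds."""


class FormatError(ValueError):
    """An input table is structurally malformed (bad header, gaps, duplicates)."""


class ModelError(ValueError):
    """A cohort model is internally inconsistent (e.g. non-stochastic row)."""


class NoCrossingError(ValueError):
    """A threshold search bracket does not contain a sign change."""
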