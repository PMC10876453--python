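"""Exception hierarchy shared by all orchid modules."""


class OrchidError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(OrchidError):
    """A scoring configuration violates an invariant (missing group, bad rating...)."""


class SchemaError(OrchidError):
    """An input table row violates the documented schema; message carries the row."""


class CohortError(OrchidError):
    """Cohort-level inconsistency (missing individual/group, mismatched spec...)."""
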