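"""Exception hierarchy shared across the pipeline stages."""


class TelecarbonError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TelecarbonError, ValueError):
    """A configuration value is invalid; the message names the offending field."""


class SchemaError(TelecarbonError, ValueError):
    """An input table is missing a required column or has a bad header."""


class DomainError(TelecarbonError, ValueError):
    """An argument is outside the operation's mathematical domain."""


class RoutingError(TelecarbonError, RuntimeError):
    """A router failed for one session; carries the session id."""

    def __init__(self, session_id: str, cause: str):
        self.session_id = session_id
        super().__init__(f"routing failed for session {session_id!r}: {cause}")
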