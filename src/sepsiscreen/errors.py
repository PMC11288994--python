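"""Package-level exception types."""


class ConfigurationError(ValueError):
    """An invalid configuration value; message names the offending field."""


class MissingVitalError(ValueError):
    """A score was requested but a required vital sign is missing."""

    def __init__(self, vital: str, tool: str | None = None):
        self.vital = vital
        self.tool = tool
        where = f" for {tool}" if tool else ""
        super().__init__(f"undefined score{where}: required vital '{vital}' is missing")
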