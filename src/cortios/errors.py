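"""Exception types shared across the package."""


class CortiosError(Exception):
    """Base class for all package-specific errors."""


class ScheduleError(CortiosError, ValueError):
    """A stimulus schedule is inconsistent with the frame stack it addresses."""


class FormatError(CortiosError, OSError):
    """An on-disk stack, sidecar, or log does not match its declared layout."""
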