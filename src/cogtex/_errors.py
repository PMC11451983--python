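"""Exception hierarchy."""


class CogtexError(Exception):
    """Base class for all package errors."""


class FormatError(CogtexError):
    """A file does not conform to its declared format; message locates the defect."""


class ConfigError(CogtexError):
    """An invalid configuration or parameter combination."""
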