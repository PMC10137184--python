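"""Exception hierarchy used across the pipeline."""


class MirdxError(Exception):
    """Base class for all package errors."""


class ValidationError(MirdxError):
    """Invalid parameter values or inconsistent inputs."""


class FormatError(MirdxError):
    """Malformed input file."""
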