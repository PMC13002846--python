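"""Exception types shared across the package."""


class ComorbnetError(ValueError):
    """Base class for all package-specific errors."""


class MalformedCodeError(ComorbnetError):
    """An ICD-10 code string does not reduce to letter + two digits."""

    def __init__(self, raw_code: str):
        self.raw_code = raw_code
        super().__init__(f"malformed ICD-10 code: {raw_code!r}")


class SpecError(ComorbnetError):
    """A synthetic-cohort or pipeline specification is invalid."""


class PipelineError(ComorbnetError):
    """A pipeline stage failed; the message is prefixed with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"{stage}: {message}")
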