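"""Exceptions shared across the pipeline stages."""


class PipelineError(RuntimeError):
    """An analysis stage failed on the given inputs.

    Carries the name of the failing stage so that the stepwise optimizer can
    report which analysis choice broke and treat it as non-improving.
    """

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"{stage}: {message}")
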