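"""Typed exceptions raised across the pipeline stages."""


class AlphaPhaseError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(AlphaPhaseError):
    """Session design violates its structural invariants."""


class ResolutionError(AlphaPhaseError):
    """Stimulus raster cannot represent the requested spatial-frequency band."""


class EmptyDataError(AlphaPhaseError):
    """All trials were rejected / no data left to analyse."""


class NoAlphaPeakError(AlphaPhaseError):
    """No discernible alpha peak inside the search band (inclusion criterion)."""


class EdgeArtifactError(AlphaPhaseError):
    """Epoch too short for the requested FIR filter."""


class DegenerateTestError(AlphaPhaseError):
    """A statistical test is undefined for the given inputs (e.g. zero variance)."""


class PipelineStageError(AlphaPhaseError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
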