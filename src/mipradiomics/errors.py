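"""Exception hierarchy shared across the pipeline stages."""


class MipRadiomicsError(Exception):
    """Base class for all package errors."""


class ContractError(MipRadiomicsError, ValueError):
    """An input violated a documented precondition (shape, emptiness, range)."""


class FormatError(MipRadiomicsError, ValueError):
    """A file could be read but its content is inconsistent (e.g. DICOM gaps)."""


class SegmentationError(MipRadiomicsError, RuntimeError):
    """A segmentation stage could not produce a usable mask."""


class GenerationError(MipRadiomicsError, RuntimeError):
    """Synthetic-data generation failed after bounded retries."""


class ConfigError(MipRadiomicsError, ValueError):
    """A run configuration failed validation."""


class PipelineError(MipRadiomicsError, RuntimeError):
    """A pipeline stage aborted; carries the stage name and case id."""

    def __init__(self, stage: str, case_id: str, message: str):
        super().__init__(f"stage '{stage}' failed for case '{case_id}': {message}")
        self.stage = stage
        self.case_id = case_id
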