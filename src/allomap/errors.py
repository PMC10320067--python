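"""Exception hierarchy for the allostery-mapping pipeline.

Every stage raises a subclass of :class:`AllomapError` so the pipeline
driver can surface the failing stage with a machine-readable code.
"""


class AllomapError(Exception):
    """Base class; ``code`` is a short machine-readable identifier."""

    code = "error"


class PdbParseError(AllomapError):
    code = "pdb-parse"


class StructureSizeError(AllomapError):
    code = "size-limit"


class EmptyStructureError(AllomapError):
    code = "empty-structure"


class LigandNotFoundError(AllomapError):
    code = "ligand-not-found"


class AmbiguousLigandError(AllomapError):
    """Empty ligand spec with more than one candidate hetero group."""

    code = "ligand-ambiguous"

    def __init__(self, candidates):
        self.candidates = list(candidates)
        names = ", ".join(str(c) for c in self.candidates)
        super().__init__(f"orthosteric ligand is ambiguous; candidates: {names}")


class DegenerateNetworkError(AllomapError):
    code = "degenerate-network"


class DisconnectedNetworkError(AllomapError):
    code = "disconnected-network"


class NumericalDegeneracyError(AllomapError):
    code = "numerical-degeneracy"


class MappingError(AllomapError):
    """A residue expected in a matrix/structure is missing."""

    code = "residue-mapping"


class EmptyProfileError(AllomapError):
    code = "empty-profile"


class TrainingError(AllomapError):
    code = "training"


class FeatureValidationError(AllomapError):
    code = "feature-validation"


class ConsistencyError(AllomapError):
    code = "inconsistent-inputs"


class UnreachableLigandError(AllomapError):
    code = "unreachable-ligand"


class UnreachableSinkError(AllomapError):
    code = "unreachable-sink"


class ParameterError(AllomapError):
    code = "bad-parameter"


class ConfigError(AllomapError):
    code = "bad-config"


class PipelineError(AllomapError):
    """Wraps a stage failure with the stage name and underlying code."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        self.code = getattr(cause, "code", "error")
        super().__init__(f"pipeline stage '{stage}' failed [{self.code}]: {cause}")
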