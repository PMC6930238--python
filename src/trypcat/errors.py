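"""Exception hierarchy shared across the package."""


class TrypcatError(Exception):
    """Base class for all package errors."""


class FormatError(TrypcatError):
    """An input file does not conform to its documented dialect."""


class ManifestError(TrypcatError):
    """The genome-collection manifest is inconsistent."""


class IntegrityError(TrypcatError):
    """Cross-references between tables do not resolve."""


class UnknownQueryTagError(TrypcatError, KeyError):
    """A homology hit references a query tag with no known length."""


class UnknownProteinError(TrypcatError, KeyError):
    """A protein id does not resolve to any gene of the genome."""


class CatalogConfigError(TrypcatError):
    """A catalog config file failed to parse."""


class CatalogValidationError(TrypcatError):
    """A catalog violates its structural invariants."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class NormalizationError(TrypcatError):
    """A sample cannot be normalized (e.g. all-zero counts)."""


class PipelineStageError(TrypcatError):
    """An end-to-end pipeline stage failed; carries the stage name."""

    def __init__(self, stage, cause):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")
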