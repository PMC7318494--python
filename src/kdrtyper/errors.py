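"""Exception hierarchy."""


class KdrTyperError(Exception):
    """Base class for all package errors."""


class PanelConfigError(KdrTyperError):
    """A panel configuration file is missing fields or malformed."""


class PanelValidationError(KdrTyperError):
    """A panel violates an assay invariant (duplicate sizes, bad tails, ...)."""


class TemplateError(KdrTyperError):
    """A template sequence is empty or not strict A/C/G/T."""


class SimulationConfigError(KdrTyperError):
    """A simulation configuration is inconsistent (counts, frequencies, ...)."""


class SampleMismatchError(KdrTyperError):
    """Two call sets do not share the same sample identifiers."""

    def __init__(self, missing_in_a: list[str], missing_in_b: list[str]):
        self.missing_in_a = list(missing_in_a)
        self.missing_in_b = list(missing_in_b)
        super().__init__(
            f"sample id mismatch: missing in first set {sorted(missing_in_a)}; "
            f"missing in second set {sorted(missing_in_b)}"
        )
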