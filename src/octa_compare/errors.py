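"""Exception hierarchy for the OCT/OCTA comparison pipeline."""


class OctaError(Exception):
    """Base class for all package errors."""


class ValidationError(OctaError):
    """An input violates a structural contract (shape, sign, ordering)."""


class DegenerateInputError(OctaError):
    """A mathematically degenerate input (all-zero volume, empty mask,
    constant regressor, zero-variance differences)."""


class RegistrationError(OctaError):
    """Cross-device registration failed (no shared structure)."""
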