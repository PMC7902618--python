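"""Domain-specific exceptions.

Plain ``ValueError`` is used for ordinary invalid arguments; the classes
below mark failure modes a caller may want to catch specifically.
"""


class ReconstructionError(ValueError):
    """Biomass reconstruction is impossible (e.g. no defined density pixels)."""


class UndefinedLossError(ValueError):
    """Relative biomass loss is undefined (pre-disturbance maximum is zero)."""


class InsufficientDataError(ValueError):
    """Too few eligible records/bins to fit the requested model."""

    def __init__(self, message: str, pft: str | None = None):
        super().__init__(message)
        self.pft = pft
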