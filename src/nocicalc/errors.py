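"""Exception hierarchy used across the package."""


class NocicalcError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(NocicalcError):
    """Invalid or inconsistent configuration (bad parameter values, unknown keys)."""


class InputError(NocicalcError):
    """Malformed or empty input data (stacks, tables, count matrices)."""


class ProtocolError(NocicalcError):
    """Stimulation protocol inconsistent with the recording (empty windows, overlap)."""


class PairingError(NocicalcError):
    """Mismatched cell sets or missing well/threshold pairing."""


class PlacementError(NocicalcError):
    """Cell positions violate rendering constraints (out of frame, overlapping spots)."""


class InsufficientControlError(NocicalcError):
    """Too few control ΔF values to estimate a noise threshold."""


class EmptyWellError(NocicalcError):
    """A well summary was requested for zero cells."""


class StatisticsError(NocicalcError):
    """Statistical comparison impossible (e.g. fewer than two replicates)."""
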