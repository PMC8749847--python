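"""Exception hierarchy shared by all gaitmood modules.

Exit-code mapping used by the CLI: ConfigError -> 2, FormatError and
StratificationError -> 3, InvariantError -> 4, everything else -> 1.
"""


class GaitmoodError(Exception):
    """Base class for all gaitmood errors."""


class ConfigError(GaitmoodError):
    """Invalid or inconsistent configuration values."""


class FormatError(GaitmoodError):
    """Malformed input file (CSV header, sidecar, manifest...)."""


class ContractError(GaitmoodError):
    """A call violated an operation's pre-condition (shape, range...)."""


class GeometryError(GaitmoodError):
    """Topology too small for the requested geometric feature."""


class StratificationError(GaitmoodError):
    """Stratified splitting is impossible for the given class profile."""


class UndefinedMetricError(GaitmoodError):
    """A metric is undefined for the given inputs (e.g. zero samples)."""


class InvariantError(GaitmoodError):
    """An internal invariant check failed at run time."""


class VersionError(GaitmoodError):
    """Persisted model/manifest incompatible with the requested load."""
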