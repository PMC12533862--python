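"""Exception hierarchy for docktriage."""


class DockTriageError(Exception):
    """Base class for all docktriage errors."""


class FormatError(DockTriageError):
    """A structure/series file could not be parsed as its declared format."""


class NotSameMoleculeError(DockTriageError):
    """Two poses do not share a heavy-atom element multiset / topology."""


class MappingExplosionError(DockTriageError):
    """The number of symmetry mappings exceeded the configured cap."""

    def __init__(self, cap: int):
        self.cap = cap
        super().__init__(
            f"number of element/bond-preserving atom mappings exceeds the cap "
            f"of {cap}; raise the cap if this molecule's symmetry is genuine"
        )


class UnknownElementError(DockTriageError):
    """An element symbol has no covalent radius in the lookup table."""

    def __init__(self, symbol: str):
        self.symbol = symbol
        super().__init__(f"unknown element symbol: {symbol!r}")


class TriageError(DockTriageError):
    """Invalid input to the screen-triage stage (duplicate ids, missing columns...)."""


class StabilityError(DockTriageError):
    """Invalid input to the MD-stability stage."""


class ConfigError(DockTriageError):
    """Invalid or unknown keys in a run configuration."""
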