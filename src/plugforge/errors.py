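"""Exception hierarchy.

ConfigError maps to CLI exit code 2, DataError (and subclasses) to exit code 3.
"""


class PlugforgeError(Exception):
    """Base class for all plugforge errors."""


class ConfigError(PlugforgeError):
    """Invalid configuration or parameters."""


class DataError(PlugforgeError):
    """Invalid or inconsistent input data."""


class PhantomGeometryError(DataError):
    """Requested phantom geometry cannot be realized (branch exits the volume,
    vessel tube collides with an airway lumen, ...)."""


class NoEligibleSite(DataError):
    """No airway lumen voxel satisfies the seed eligibility constraints.

    Callers may catch this and resample the plug phenotype."""


class NoCompanion(DataError):
    """No vessel of comparable caliber found within the search radius."""
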