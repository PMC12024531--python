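"""Exception vocabulary shared across the toolkit."""


class ShapeError(ValueError):
    """A network shape chain produced a non-positive spatial side."""


class MarginError(ValueError):
    """A crop or rotation window does not fit inside the source frame."""


class ConfigError(ValueError):
    """An invalid configuration value or combination."""


class GeometryError(ValueError):
    """Phantom geometry that cannot be rendered (e.g. lesion outside frame)."""


class DataError(ValueError):
    """Malformed dataset, manifest, or prediction inputs."""
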