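"""Exception types shared across the package."""


class BoneAtlasError(Exception):
    """Base class for all package errors."""


class MeshIOError(BoneAtlasError):
    """Malformed or unreadable mesh / landmark / volume file."""


class GeometryError(BoneAtlasError):
    """Invalid geometric input (non-watertight mesh, empty volume, ...)."""


class RegistrationError(BoneAtlasError):
    """A registration engine failed or diverged."""


class ValidationError(BoneAtlasError):
    """Invalid arguments to an analysis operation."""
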