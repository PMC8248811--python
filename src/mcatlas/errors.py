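"""Exception types shared across the package."""


class McatlasError(Exception):
    """Base class for all package errors."""


class InvalidOrderError(McatlasError, ValueError):
    """Spherical-harmonic order is invalid (odd or negative)."""


class InvalidDirectionError(McatlasError, ValueError):
    """A direction vector is degenerate (zero norm) or not unit length."""


class InvalidRotationError(McatlasError, ValueError):
    """A matrix passed as a rotation is not a proper rotation."""


class GridMismatchError(McatlasError, ValueError):
    """Two images do not share grid shape and voxel-to-world affine."""


class ChannelIncompatibilityError(McatlasError, ValueError):
    """Channel structure (names, roles, lmax) differs between inputs."""


class InvalidFieldError(McatlasError, ValueError):
    """A displacement field contains non-finite values."""


class ConfigurationError(McatlasError, ValueError):
    """Inconsistent configuration or argument counts."""


class InsufficientDataError(McatlasError, ValueError):
    """Too few inputs for the requested operation."""


class RegistrationError(McatlasError, RuntimeError):
    """Registration failed (no overlap, divergence, non-convergence)."""


class FormatError(McatlasError, ValueError):
    """A file's contents do not match any supported layout."""
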