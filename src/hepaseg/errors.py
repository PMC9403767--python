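"""Exception hierarchy for hepaseg."""


class HepasegError(Exception):
    """Base class for all hepaseg errors."""


class FormatError(HepasegError, ValueError):
    """A file is unreadable or not a supported 3D NIfTI image."""


class AlignmentError(HepasegError, ValueError):
    """Two volumes that must share a grid (shape, spacing, origin) do not."""


class DegenerateHistogramError(HepasegError, ValueError):
    """The in-liver intensity histogram has no usable half-maximum crossings."""


class ConfigError(HepasegError, ValueError):
    """An architecture/training configuration is invalid or inconsistent."""


class ResourceError(HepasegError, RuntimeError):
    """A requested external resource (e.g. a pretrained-weight file) is missing."""
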