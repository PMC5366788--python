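"""Exception hierarchy shared across the toolkit."""


class AtlasError(Exception):
    """Base class for all atlaskit errors."""


class AtlasFormatError(AtlasError, ValueError):
    """The atlas document violates the format contract."""


class MissingHeaderError(AtlasFormatError):
    """No Header node was found in the document."""


class DuplicateIDError(AtlasFormatError):
    """Two nodes share the same ID."""


class DanglingReferenceError(AtlasFormatError):
    """An attribute references an ID that resolves to no node."""


class UnknownIDError(AtlasError, KeyError):
    """Lookup of an ID that is not present in the graph."""


class UnreachableNodeError(AtlasError):
    """A hierarchy query was made for a node not reachable from any root."""


class MeshFormatError(AtlasError, ValueError):
    """A geometry file is malformed or in an unsupported format."""


class VolumeError(AtlasError, ValueError):
    """A volumetric file or operation violates its contract."""


class ConversionError(AtlasError, ValueError):
    """TSV-to-atlas conversion failed."""


class UnknownBookmarkError(AtlasError, KeyError):
    """Lookup of a bookmark UUID that is not in the store."""


class BookmarkPermissionError(AtlasError, PermissionError):
    """A store operation was attempted by a non-owner."""
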