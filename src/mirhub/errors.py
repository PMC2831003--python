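"""Exception types shared across the package."""


class MirhubError(Exception):
    """Base class for all package-specific errors."""


class NotFoundError(MirhubError, LookupError):
    """No entity with the requested identifier exists."""

    def __init__(self, kind: str, identifier: str):
        super().__init__(f"no {kind} with identifier {identifier!r}")
        self.kind = kind
        self.identifier = identifier


class UnknownKindError(MirhubError, ValueError):
    """The requested entity kind is not registered."""

    def __init__(self, kind: str, known=()):
        msg = f"unknown entity kind {kind!r}"
        if known:
            msg += f"; known kinds: {', '.join(sorted(known))}"
        super().__init__(msg)
        self.kind = kind


class UnknownAssociationError(MirhubError, ValueError):
    """The requested association is not declared for the entity's kind."""

    def __init__(self, kind: str, association: str, valid=()):
        msg = f"{kind!r} has no association {association!r}"
        if valid:
            msg += f"; valid associations: {', '.join(sorted(valid))}"
        super().__init__(msg)
        self.kind = kind
        self.association = association
        self.valid = tuple(sorted(valid))


class MalformedRecordError(MirhubError, ValueError):
    """A flat-file record could not be parsed.

    Carries the 1-based line number where the record starts.
    """

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class SeedTooShortError(MirhubError, ValueError):
    """Sequence too short to carry a seed of the requested length."""


class NoPositionError(MirhubError, ValueError):
    """Operation requires a genome position the precursor does not have."""


class PluginError(MirhubError):
    """Base class for plugin registration problems."""


class PluginCollisionError(PluginError):
    """A plugin declares a kind or route that already exists."""


class DanglingAssociationError(PluginError):
    """A plugin association references a kind that is not registered."""


class UnknownVersionError(MirhubError, ValueError):
    """The requested release version does not exist upstream."""


class FetchError(MirhubError, IOError):
    """A release could not be downloaded."""
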