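"""Exception hierarchy.

Every error raised by the library derives from :class:`PathnetError`, so
callers (and the CLI) can distinguish usage mistakes (bad arguments,
unknown vocabulary labels) from data problems (schema violations, dangling
references) with two ``except`` clauses.
"""


class PathnetError(Exception):
    """Base class for all library errors."""


class UsageError(PathnetError):
    """The caller violated an operation's contract (bad flag combination,
    out-of-range parameter, duplicate input id)."""


class VocabularyError(UsageError):
    """A label or id is not part of the controlled vocabulary it was
    checked against (unknown role, entity type, organism, location...)."""


class NotFoundError(PathnetError):
    """A referenced object does not exist in the repository."""


class IntegrityError(PathnetError):
    """A cross-reference inside a repository document does not resolve."""


class ValidationError(PathnetError):
    """A repository document violates the schema.

    ``path`` is a JSON-pointer-style location of the offending value.
    """

    def __init__(self, message: str, path: str = ""):
        super().__init__(f"{path}: {message}" if path else message)
        self.path = path
        self.reason = message


class ConflictError(PathnetError):
    """A write would collide with an existing record (e.g. publishing a
    pathway under a name already used for the same organism)."""


class ExportError(PathnetError):
    """An export cannot be produced faithfully (e.g. sanitized ids collide)."""
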