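"""Exception hierarchy shared across the package."""


class TreelinkError(Exception):
    """Base class for all errors raised by treelink."""


class ValidationError(TreelinkError, ValueError):
    """Structural invariant violated (duplicate labels, shape mismatch, ...)."""


class NodeResolveError(TreelinkError, KeyError):
    """A node reference (label or number) could not be resolved in a tree."""

    def __init__(self, ref):
        self.ref = ref
        super().__init__(f"node reference {ref!r} cannot be resolved in this tree")

    def __str__(self):  # KeyError quotes its repr otherwise
        return self.args[0]


class NewickParseError(TreelinkError, ValueError):
    """Malformed Newick input; carries a character offset when known."""

    def __init__(self, message, offset=None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at character offset {offset})"
        super().__init__(message)


class BundleError(TreelinkError, ValueError):
    """Inconsistent or missing files in an on-disk container bundle."""
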