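"""Exception hierarchy."""


class AllokitError(Exception):
    """Base class for all package errors."""


class StructureError(AllokitError):
    """Malformed or unusable input structure (no CA atoms, too few residues...)."""


class DisconnectedStructureError(AllokitError):
    """The contact network is disconnected or geometrically degenerate.

    Carries the residue-index partition of connected components when known.
    """

    def __init__(self, message, components=None):
        super().__init__(message)
        self.components = components or []


class ValidationError(AllokitError):
    """Invalid user input: unknown residue, bad perturbation spec, shape mismatch."""
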