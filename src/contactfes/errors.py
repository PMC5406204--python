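"""Exception hierarchy for contactfes."""


class ContactFESError(Exception):
    """Base class for all package errors."""


class FormatError(ContactFESError, ValueError):
    """A file does not conform to its declared text format."""


class SelectionError(ContactFESError, ValueError):
    """Malformed atom-selection expression."""


class DegenerateFitError(ContactFESError, ValueError):
    """Superposition requested on fewer than 3 atoms or a collinear set."""


class ResidueLookupError(ContactFESError, KeyError):
    """A referenced residue or atom is absent from the structure."""


class ConsistencyError(ContactFESError, ValueError):
    """Inputs that must agree (atom identities, grid shapes, bias factors) do not."""


class ConfigurationError(ContactFESError, ValueError):
    """An engine or analysis was configured incoherently."""


class ConstraintError(ContactFESError, RuntimeError):
    """A synthetic-data generator could not satisfy its planted constraints."""
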