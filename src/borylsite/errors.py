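"""Exception hierarchy for the borylation site-selectivity pipeline."""


class BorylsiteError(Exception):
    """Base class for all package errors."""


class ParseError(BorylsiteError):
    """A structure string (SMILES or InChI) could not be parsed."""

    def __init__(self, structure_text: str, message: str | None = None):
        self.structure_text = structure_text
        super().__init__(message or f"could not parse structure: {structure_text!r}")


class SchemaError(BorylsiteError):
    """A table is missing mandatory columns or has mismatched columns."""


class IntegrityError(BorylsiteError):
    """A table violates a dataset invariant (duplicate sites, multiple labels)."""


class RegistryError(BorylsiteError):
    """A catalyst / ligand / solvent name is not in the shipped registry."""


class ParameterLookupError(BorylsiteError):
    """A catalyst-ligand pair has no row in the parameter table."""


class AssemblyError(BorylsiteError):
    """Feature-matrix assembly failed (missing feature or missing value)."""


class ConfigError(BorylsiteError):
    """An invalid model / protocol / generator configuration value."""


class UnsupportedModelError(BorylsiteError):
    """Operation requested on a model type that does not support it."""
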