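"""Exception hierarchy shared across the package."""


class PalsymetryError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(PalsymetryError):
    """A landmark file does not conform to the CSV/JSON schema."""


class ValidationError(PalsymetryError):
    """An in-memory object violates a structural invariant."""


class DegenerateGeometryError(PalsymetryError):
    """A geometric construction is undefined (coincident points, zero area...)."""


class SequenceTooShortError(PalsymetryError):
    """The clip has too few frames for the requested displacement window."""


class FixtureIntegrityError(PalsymetryError):
    """A packaged data fixture failed its checksum."""
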