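"""Exception hierarchy.

All exceptions raised deliberately by this package derive from
:class:`FairdsError` so callers can catch one base class. Validation
*findings* are data (see :mod:`fairds.validation`), never exceptions.
"""


class FairdsError(Exception):
    """Base class for all fairds errors."""


class LibraryFormatError(FairdsError):
    """The package-library workbook is malformed (names sheet/row)."""


class PackageLookupError(FairdsError, KeyError):
    """A package id does not exist in the library."""

    def __str__(self) -> str:  # KeyError quotes its args; keep the message readable
        return Exception.__str__(self)


class SelectionError(FairdsError):
    """An optional-attribute selection names attributes the package lacks."""


class StructuralError(FairdsError):
    """A workbook is missing a required sheet or identifier column."""


class RecordLookupError(FairdsError, KeyError):
    """A record identifier does not exist at the requested hierarchy level."""

    def __str__(self) -> str:
        return Exception.__str__(self)


class ConfigurationError(FairdsError):
    """Required run configuration is missing (e.g. an ontology index)."""


class OntologyError(FairdsError):
    """An ontology document could not be retrieved or parsed."""


class ConversionError(FairdsError):
    """Project metadata cannot be converted to an ENA submission set."""


class QueryError(FairdsError):
    """A SPARQL query is malformed or uses unsupported syntax."""
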