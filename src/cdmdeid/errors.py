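"""Exception hierarchy; the CLI maps these onto exit codes."""


class CdmDeidError(Exception):
    """Base class for all package errors."""


class ConfigError(CdmDeidError):
    """Invalid run configuration or generator configuration (CLI exit code 2)."""


class UnregisteredTableError(CdmDeidError):
    """Lookup against a table the schema registry does not know."""

    def __init__(self, table: str):
        super().__init__(f"unregistered table: {table!r}")
        self.table = table


class InfeasibleModelError(CdmDeidError):
    """No generalization node satisfies the privacy model within the
    suppression limit (CLI exit code 3)."""


class DataFormatError(CdmDeidError):
    """Malformed input file (CLI exit code 4)."""
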