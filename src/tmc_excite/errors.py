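"""Exception hierarchy shared across the pipeline."""


class TmcExciteError(Exception):
    """Base class for all package errors."""


class InputError(TmcExciteError, ValueError):
    """Invalid scalar or container input (non-finite wavelength, bad range...)."""


class SchemaError(TmcExciteError, ValueError):
    """CSV header does not match the expected Table-1-style schema."""


class RecordError(TmcExciteError, ValueError):
    """A single row/record could not be read; carries the row identifier."""


class ParseError(TmcExciteError, ValueError):
    """Malformed excited-state text block (e.g. duplicate state index)."""


class DegenerateNTOError(TmcExciteError, ValueError):
    """Both moiety densities vanish; the relative contribution is undefined."""


class MissingNTOError(TmcExciteError, ValueError):
    """A record is eligible for CT classification but has no NTO data."""


class GenerationError(TmcExciteError, ValueError):
    """A synthetic record with the requested ground truth is infeasible."""
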