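"""Exception types raised across mirrorkit."""


class MirrorkitError(Exception):
    """Base class for all mirrorkit errors."""


class MDBFormatError(MirrorkitError, ValueError):
    """A prediction-database table violates the expected TSV dialect."""


class EmptyInputError(MirrorkitError, ValueError):
    """A required input table carries no rows."""


class EmptyQueryError(MirrorkitError, ValueError):
    """No query identifier survived mapping/normalization."""


class EmptyBackgroundError(MirrorkitError, ValueError):
    """A context restriction removed every gene from the background."""


class ConfigError(MirrorkitError, ValueError):
    """A synthetic-data or run configuration is internally inconsistent."""
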