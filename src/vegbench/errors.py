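"""Exception types shared across vegbench modules."""


class VegbenchError(Exception):
    """Base class for all vegbench errors."""


class ConfigurationError(VegbenchError):
    """A user-supplied table, mapping, or model configuration is invalid."""


class DataError(VegbenchError):
    """Input data violate a precondition (bad values, missing coverage, bad indices)."""
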