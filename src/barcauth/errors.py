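"""Exception hierarchy for barcauth."""


class BarcauthError(Exception):
    """Base class for all barcauth errors."""


class ParseError(BarcauthError):
    """A file or token did not parse under the documented dialect."""


class DataError(BarcauthError):
    """Input data violated a documented invariant (ragged alignment, duplicate id...)."""


class AnchorError(BarcauthError):
    """A conserved anchor motif was absent or matched more than once."""
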