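"""Exception hierarchy for ptmvar.

Every error the library raises deliberately derives from :class:`PtmvarError`
so callers (and the CLI) can catch the package's own failures without
swallowing programming errors.
"""


class PtmvarError(Exception):
    """Base class for all ptmvar errors."""


class FlatfileFormatError(PtmvarError):
    """The protein flat file is structurally invalid (e.g. missing column)."""


class HumsavarFormatError(PtmvarError):
    """The humsavar-style variant file has no recognizable data block."""


class UnknownAccessionError(PtmvarError, KeyError):
    """An accession was looked up that no record (primary or alternate) owns."""

    def __init__(self, accession: str):
        super().__init__(accession)
        self.accession = accession

    def __str__(self) -> str:  # KeyError quotes its arg; keep message readable
        return f"unknown accession: {self.accession!r}"


class DegenerateTableError(PtmvarError, ValueError):
    """A contingency table with zero total cannot be tested."""


class EmptyForegroundError(PtmvarError):
    """No pathogenic/disease mutations exist, so no foreground can be formed."""


class UndefinedFractionError(PtmvarError, ValueError):
    """A fraction was requested over an empty variant list."""


class InfeasibleCompositionError(PtmvarError):
    """The candidate pool cannot supply a composition-matched sample."""

    def __init__(self, residue: str, requested: int, available: int):
        self.residue = residue
        self.requested = requested
        self.available = available
        super().__init__(
            f"cannot draw {requested} residues of type {residue!r}: only "
            f"{available} available (shortfall {requested - available}); "
            "consider downsampling the target composition proportionally"
        )
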