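"""Exception hierarchy shared across ampliscope modules."""


class AmpliscopeError(Exception):
    """Base class for all ampliscope errors."""


class InvalidAlphabetError(AmpliscopeError):
    """A sequence contains a character outside the 15-letter IUPAC DNA alphabet."""

    def __init__(self, char: str, position: int, context: str = ""):
        self.char = char
        self.position = position
        msg = f"invalid IUPAC DNA character {char!r} at position {position}"
        if context:
            msg += f" in {context}"
        super().__init__(msg)


class DegeneracyCapError(AmpliscopeError):
    """Expansion refused because the degeneracy exceeds the configured cap."""


class DataError(AmpliscopeError):
    """Malformed or inconsistent input data (duplicate IDs, empty FASTA, ...)."""
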