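"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3.
"""


class InvertiscanError(Exception):
    """Base class for all package errors."""


class ConfigError(InvertiscanError, ValueError):
    """Invalid parameter values or parameter ordering."""


class DataError(InvertiscanError, ValueError):
    """Malformed or inconsistent input data."""


class DNAAlphabetError(DataError):
    """A sequence contains a character outside {A, C, G, T, N}."""

    def __init__(self, char: str, position: int, context: str = ""):
        self.char = char
        self.position = position
        where = f" in {context}" if context else ""
        super().__init__(
            f"non-DNA character {char!r} at position {position}{where} "
            "(allowed alphabet: A, C, G, T, N)"
        )


class AmbiguousPlacementError(DataError):
    """A locus qualifies at more than one non-overlapping genomic placement."""

    def __init__(self, locus_name: str, candidates):
        self.locus_name = locus_name
        self.candidates = list(candidates)
        desc = ", ".join(f"{c[0]}:{c[1]}-{c[2]}({c[3]})" for c in self.candidates)
        super().__init__(
            f"locus {locus_name!r} has {len(self.candidates)} non-overlapping "
            f"qualifying placements: {desc}"
        )
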