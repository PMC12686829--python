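"""96-channel single-base-substitution spectra.

The channel order is fixed and documented here once, because catalogs in the
wild disagree: substitution-major (C>A, C>G, C>T, T>A, T>C, T>G), and within
each substitution the 16 trinucleotide flanks in alphabetical order of
(5' base, 3' base).  Mutations with a purine reference base are mapped onto
the pyrimidine strand by reverse complement before counting.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTIONS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]

#: Fixed channel order, e.g. "A[C>A]A", "A[C>A]C", ... "T[T>G]T".
CHANNELS = [
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
]
CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}

N_CHANNELS = 96

_CONTEXT_RE = re.compile(r"^([ACGT])\[([ACGT])>([ACGT])\]([ACGT])$")


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def canonical_channel(five: str, ref: str, alt: str, three: str) -> str:
    """Return the pyrimidine-strand channel label for a substitution.

    Purine-reference mutations are reverse-complemented, so e.g.
    (G, A, T, C) — the context G[A>T]C — counts as G[T>A]C.
    """
    if ref in "AG":
        five, three = COMPLEMENT[three], COMPLEMENT[five]
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    label = f"{five}[{ref}>{alt}]{three}"
    if label not in CHANNEL_INDEX:
        raise ValueError(f"not a valid substitution channel: {label}")
    return label


def parse_context(context: str) -> tuple[str, str, str, str]:
    """Parse a context string like ``"A[C>T]G"`` into (five, ref, alt, three)."""
    m = _CONTEXT_RE.match(context.strip())
    if m is None:
        raise ValueError(f"malformed trinucleotide context: {context!r}")
    five, ref, alt, three = m.groups()
    if ref == alt:
        raise ValueError(f"reference equals alternate in context: {context!r}")
    return five, ref, alt, three


def count_spectrum(contexts, on_error: str = "warn") -> np.ndarray:
    """Count mutation contexts into a 96-channel vector.

    Parameters
    ----------
    contexts
        Iterable of context strings (``"A[C>T]G"``) or
        ``(five, ref, alt, three)`` tuples.  Purine-reference entries are
        strand-flipped.
    on_error
        ``"warn"`` rejects malformed records with a warning, ``"raise"``
        propagates the error.
    """
    import warnings

    counts = np.zeros(N_CHANNELS, dtype=float)
    for ctx in contexts:
        try:
            if isinstance(ctx, str):
                five, ref, alt, three = parse_context(ctx)
            else:
                five, ref, alt, three = ctx
            counts[CHANNEL_INDEX[canonical_channel(five, ref, alt, three)]] += 1
        except (ValueError, KeyError) as exc:
            if on_error == "raise":
                raise
            warnings.warn(f"rejecting malformed mutation context: {exc}")
    return counts


def cosine(a, b) -> float:
    """Cosine similarity between two nonnegative spectra (0 if either is 0)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a @ b / (na * nb))


def spectrum_frame(columns: dict[str, np.ndarray]) -> pd.DataFrame:
    """Assemble named spectra into a channels x samples DataFrame."""
    df = pd.DataFrame(columns, index=CHANNELS)
    df.index.name = "channel"
    return df


def read_spectra_tsv(path) -> pd.DataFrame:
    """Read a channels-as-rows TSV, reordering rows into the fixed order."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CHANNELS) - set(df.index)
    if missing:
        raise ValueError(f"spectrum TSV missing {len(missing)} channels")
    return df.loc[CHANNELS]


def write_spectra_tsv(df: pd.DataFrame, path) -> None:
    df.loc[CHANNELS].to_csv(path, sep="\t")
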