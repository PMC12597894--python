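"""Decoy peptide generation by terminal-adjacent residue mutation.

Each target peptide is paired with exactly one decoy obtained by substituting
the two residues adjacent to the termini (1-based positions 2 and L-1)
according to a fixed 20-letter replacement table, the scheme Beta-DIA uses::

    source      G A V L I F M P W S C T Y H K R Q E N D
    replacement L L L V V L L L L T S S S S L L N D Q E

The table has no fixed points, so a decoy always differs from its target
(Hamming distance exactly 2 for any peptide of length >= 4), and pairing is
1:1 by construction. Note S<->T, Q<->N and E<->D are involutions: mutating
twice restores those residues.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .exceptions import SequenceLengthError, UnsupportedResidueError

#: the 20 standard amino-acid letters, and the positional replacement pattern
MUTATION_SOURCE = "GAVLIFMPWSCTYHKRQEND"
MUTATION_REPLACEMENT = "LLLVVLLLLTSSSSLLNDQE"

#: default source -> replacement table, read positionally from the two strings
DEFAULT_MUTATION_MAP: dict[str, str] = dict(
    zip(MUTATION_SOURCE, MUTATION_REPLACEMENT)
)

STANDARD_AA = frozenset(MUTATION_SOURCE)

# minimum length so both mutated positions are interior and distinct
MIN_PEPTIDE_LENGTH = 4


def _check_map(mapping: Mapping[str, str]) -> Mapping[str, str]:
    if set(mapping) != STANDARD_AA:
        raise ValueError(
            "mutation map domain must be exactly the 20 standard amino acids"
        )
    fixed = sorted(a for a, b in mapping.items() if a == b)
    if fixed:
        raise ValueError(f"mutation map has fixed points: {fixed}")
    return mapping


def mutate_residue(aa: str, mapping: Mapping[str, str] | None = None) -> str:
    """Replace one standard amino-acid letter according to the mutation table."""
    mapping = DEFAULT_MUTATION_MAP if mapping is None else mapping
    try:
        return mapping[aa]
    except KeyError:
        raise UnsupportedResidueError(
            f"residue {aa!r} is not one of the 20 standard amino acids"
        ) from None


def generate_decoy(seq: str, mapping: Mapping[str, str] | None = None) -> str:
    """Return the decoy of ``seq``: positions 2 and len-1 (1-based) mutated.

    The sequence must be at least {MIN} residues long so the two mutated
    positions exist and are distinct; all residues must be standard letters.
    """
    mapping = _check_map(DEFAULT_MUTATION_MAP if mapping is None else mapping)
    if len(seq) < MIN_PEPTIDE_LENGTH:
        raise SequenceLengthError(
            f"peptide {seq!r} has length {len(seq)}; the mutation scheme "
            f"needs length >= {MIN_PEPTIDE_LENGTH}"
        )
    bad = sorted(set(seq) - STANDARD_AA)
    if bad:
        raise UnsupportedResidueError(
            f"peptide {seq!r} contains non-standard residue(s) {bad}"
        )
    chars = list(seq)
    chars[1] = mapping[chars[1]]
    chars[-2] = mapping[chars[-2]]
    return "".join(chars)


generate_decoy.__doc__ = generate_decoy.__doc__.replace("{MIN}", str(MIN_PEPTIDE_LENGTH))  # type: ignore[union-attr]


def attach_decoys(
    targets: Iterable[str], mapping: Mapping[str, str] | None = None
) -> list[tuple[str, str]]:
    """Pair every target peptide with its decoy, preserving order.

    Guarantees a 1:1 target:decoy ratio: the output has exactly one
    ``(target, decoy)`` pair per input sequence. Per-sequence failures are
    re-raised with the offending index.
    """
    pairs: list[tuple[str, str]] = []
    for i, seq in enumerate(targets):
        try:
            pairs.append((seq, generate_decoy(seq, mapping)))
        except (SequenceLengthError, UnsupportedResidueError) as exc:
            raise type(exc)(f"target at index {i}: {exc}") from None
    return pairs


def decoy_table(targets: Sequence[str]) -> list[dict[str, str]]:
    """Rows for a two-column TSV of (target, decoy) pairs."""
    return [{"target": t, "decoy": d} for t, d in attach_decoys(targets)]
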