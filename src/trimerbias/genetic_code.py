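"""Standard genetic code and the 12-class amino-acid characteristic alphabet.

The classifier reads DNA nine nucleotides at a time as three in-frame codons
(a "3-codon 9-mer") and works with two coarser views of the encoded residue
trimer: the amino-acid trimer itself and its *characteristic* trimer, obtained
by mapping each residue into one of 12 physicochemical classes (charge,
polarity and side-chain volume; cysteine, glycine, histidine, methionine and
proline each form their own class, and the stop signal has a class of its
own).  These three views form the hierarchy the reference database is keyed
by.
"""

from __future__ import annotations

from Bio.Data import CodonTable

__all__ = [
    "STOP",
    "DNA_ALPHABET",
    "CODON_TO_AA",
    "AA_TO_CODONS",
    "AA_CHAR",
    "CHAR_MEMBERS",
    "CHAR_LABELS",
    "translate_codon",
    "char_of",
    "ninemer_to_trimer",
    "trimer_to_char_trimer",
    "synonymous_ninemers",
    "reverse_complement",
]

STOP = "*"
DNA_ALPHABET = frozenset("ACGT")

_standard = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter residue, with all three stop codons mapped to ``*``
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
for _stop_codon in _standard.stop_codons:
    CODON_TO_AA[_stop_codon] = STOP

#: residue (or ``*``) -> sorted list of synonymous codons
AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, []).append(_codon)

#: residue (or ``*``) -> characteristic class label.
#: Positively charged K,R -> A; special H -> B; negatively charged D,E -> C;
#: polar uncharged small S,T -> D, larger N,Q -> E; C -> F; G -> G; P -> H;
#: M -> I; hydrophobic small A,I,L,V -> J, larger F,W,Y -> K; stop -> L.
AA_CHAR: dict[str, str] = {
    "K": "A", "R": "A",
    "H": "B",
    "D": "C", "E": "C",
    "S": "D", "T": "D",
    "N": "E", "Q": "E",
    "C": "F",
    "G": "G",
    "P": "H",
    "M": "I",
    "A": "J", "I": "J", "L": "J", "V": "J",
    "F": "K", "W": "K", "Y": "K",
    STOP: "L",
}

CHAR_LABELS = "ABCDEFGHIJKL"

#: class label -> sorted residues in the class
CHAR_MEMBERS: dict[str, list[str]] = {}
for _aa, _label in sorted(AA_CHAR.items()):
    CHAR_MEMBERS.setdefault(_label, []).append(_aa)

_RC = str.maketrans("ACGT", "TGCA")


def translate_codon(codon: str) -> str:
    """Translate one codon under the standard genetic code.

    Returns the one-letter residue code, or ``*`` for a stop codon.
    """
    codon = codon.upper()
    if len(codon) != 3 or not set(codon) <= DNA_ALPHABET:
        raise ValueError(f"invalid codon: {codon!r}")
    return CODON_TO_AA[codon]


def char_of(residue: str) -> str:
    """Map a residue (or ``*``) to its characteristic class label."""
    residue = residue.upper() if residue != STOP else residue
    try:
        return AA_CHAR[residue]
    except KeyError:
        raise ValueError(f"unknown residue: {residue!r}") from None


def ninemer_to_trimer(ninemer: str) -> str:
    """Translate a 9-nt window into its residue trimer (stops as ``*``)."""
    ninemer = ninemer.upper()
    if len(ninemer) != 9 or not set(ninemer) <= DNA_ALPHABET:
        raise ValueError(f"invalid 9-mer: {ninemer!r}")
    return "".join(CODON_TO_AA[ninemer[i : i + 3]] for i in (0, 3, 6))


def trimer_to_char_trimer(trimer: str) -> str:
    """Map a residue trimer to its characteristic trimer."""
    if len(trimer) != 3:
        raise ValueError(f"invalid trimer: {trimer!r}")
    return "".join(char_of(r) for r in trimer)


def synonymous_ninemers(trimer: str) -> list[str]:
    """Enumerate every 9-mer encoding ``trimer``, in lexicographic order."""
    out = [""]
    for residue in trimer.upper():
        codons = AA_TO_CODONS.get(residue if residue != STOP else STOP)
        if codons is None:
            raise ValueError(f"unknown residue: {residue!r}")
        out = [prefix + c for prefix in out for c in codons]
    return sorted(out)


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]
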