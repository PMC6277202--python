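"""Reduced-alphabet recoding of amino-acid alignments.

Dayhoff-6 recoding collapses the 20 amino acids into six biochemically
coherent groups — AGPST, DENQ, HKR, ILMV, FWY, C — encoded here as the
digits '0'-'5' in that order.  Collapsing groups that exchange
frequently within themselves reduces among-lineage compositional
differences at the cost of information.  The scheme registry is
extensible; custom schemes load from a two-column TSV (residue, symbol).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .seqio import AMINO_ACIDS, Alignment, NON_RESIDUE


@dataclass(frozen=True)
class RecodingScheme:
    """A partition of the 20 amino acids into labelled groups."""

    name: str
    groups: tuple[str, ...]
    output_symbols: str

    def __post_init__(self) -> None:
        if len(self.groups) != len(self.output_symbols):
            raise ValueError("one output symbol required per group")
        if len(set(self.output_symbols)) != len(self.output_symbols):
            raise ValueError("output symbols must be unique")
        pooled = "".join(self.groups)
        if sorted(pooled) != sorted(AMINO_ACIDS):
            raise ValueError(
                f"scheme {self.name!r}: groups must partition the 20 amino acids")

    @property
    def mapping(self) -> dict[str, str]:
        return {res: sym for grp, sym in zip(self.groups, self.output_symbols)
                for res in grp}


DAYHOFF6 = RecodingScheme(
    name="dayhoff6",
    groups=("AGPST", "DENQ", "HKR", "ILMV", "FWY", "C"),
    output_symbols="012345",
)

SCHEMES: dict[str, RecodingScheme] = {"dayhoff6": DAYHOFF6}


def get_scheme(name: str) -> RecodingScheme:
    try:
        return SCHEMES[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown recoding scheme {name!r}; available: {sorted(SCHEMES)}"
        ) from None


def load_scheme_tsv(path: str | Path, name: str | None = None) -> RecodingScheme:
    """Load a custom scheme from a residue -> symbol two-column TSV."""
    pairs = [ln.split("\t")[:2] for ln in Path(path).read_text().strip().splitlines()]
    by_symbol: dict[str, list[str]] = {}
    for res, sym in pairs:
        by_symbol.setdefault(sym.strip(), []).append(res.strip().upper())
    symbols = "".join(by_symbol)
    groups = tuple("".join(v) for v in by_symbol.values())
    return RecodingScheme(name or Path(path).stem, groups, symbols)


def recode_alignment(aln: Alignment, scheme: RecodingScheme = DAYHOFF6) -> Alignment:
    """Replace each residue by its group symbol; gaps/missing pass through.

    Raises if the alignment contains a symbol the scheme does not cover
    (e.g. when fed an already-recoded matrix).
    """
    table = dict(scheme.mapping)
    for ch in NON_RESIDUE:
        table[ch] = ch
    trans = str.maketrans(table)
    out = []
    for taxon, seq in zip(aln.taxa, aln.sequences):
        unknown = set(seq) - set(table)
        if unknown:
            raise ValueError(
                f"{aln.name or 'alignment'}: record '{taxon}' has characters "
                f"{sorted(unknown)} not covered by scheme {scheme.name!r}")
        out.append(seq.translate(trans))
    return Alignment(list(aln.taxa), out, name=aln.name)
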