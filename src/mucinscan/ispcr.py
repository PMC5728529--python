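"""In-silico PCR: exact primer matching and amplicon prediction.

A product is reported wherever the forward primer matches the template
exactly and the reverse complement of the reverse primer matches exactly
downstream of it (non-overlapping), mirroring how a qPCR assay amplifies
the region between its two primer sites.  Matching is exact by design —
the assays verified here are exact-match designs — so ambiguous template
bases simply never match.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

__all__ = ["PrimerPair", "Amplicon", "find_amplicon"]

DNA = set("ACGT")
MIN_PRIMER_LEN = 10


@dataclass(frozen=True)
class PrimerPair:
    """A named primer pair, both given 5'->3'."""

    name: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for which in ("forward", "reverse"):
            seq = getattr(self, which).upper()
            object.__setattr__(self, which, seq)
            if len(seq) < MIN_PRIMER_LEN:
                raise ValueError(
                    f"{self.name}: {which} primer shorter than {MIN_PRIMER_LEN} nt"
                )
            bad = set(seq) - DNA
            if bad:
                raise ValueError(
                    f"{self.name}: {which} primer has non-ACGT base(s) {sorted(bad)}"
                )


@dataclass(frozen=True)
class Amplicon:
    """A predicted product: 1-based inclusive span on the template."""

    template_id: str
    primer_name: str
    start: int  # first base of the forward primer site
    end: int    # last base of the reverse primer site

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def find_amplicon(
    template: str,
    pair: PrimerPair,
    template_id: str = "template",
    max_products: int = 10,
) -> list[Amplicon]:
    """All products of ``pair`` on ``template``, shortest first.

    The forward primer is matched on the given strand; the reverse primer
    binds the opposite strand, so its site on the template is the reverse
    complement of the primer, required to lie entirely downstream of the
    forward site.  Because PCR amplifies the duplex, the flipped
    presentation (reverse primer literal on the given strand, reverse
    complement of the forward primer downstream) is searched too, so the
    reverse complement of a template yields products of identical lengths.
    Zero products is an empty list, not an error.
    """
    tpl = template.upper()
    products: set[Amplicon] = set()
    for left, right in (
        (pair.forward, str(Seq(pair.reverse).reverse_complement())),
        (pair.reverse, str(Seq(pair.forward).reverse_complement())),
    ):
        for f in _find_all(tpl, left):
            for r in _find_all(tpl, right):
                if r >= f + len(left):
                    products.add(
                        Amplicon(
                            template_id=template_id,
                            primer_name=pair.name,
                            start=f + 1,
                            end=r + len(right),
                        )
                    )
    return sorted(products, key=lambda a: (a.length, a.start))[:max_products]
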