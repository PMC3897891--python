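"""In-silico restriction digestion and fragment-size selection for
reduced-representation library (RRL) design.

A genome is digested with a blunt-end Type II restriction enzyme, every
forward-strand occurrence of the (palindromic) recognition site contributes a
cut, and the resulting fragments tile each sequence exactly.  Selecting the
fragments inside a length window defines the sequencing target regions and the
sampled genome fraction — the design quantity an RRL experiment is built
around.

Coordinates are 0-based half-open internally and in BED output; human-readable
reports are 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RestrictionEnzyme",
    "TargetRegionSet",
    "ENZYMES",
    "digest",
    "select_fragments",
    "fragment_profile",
    "window_sensitivity",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(site: str) -> str:
    return site.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A blunt-end restriction enzyme.

    ``cut_offset`` is the number of bases of the recognition site that lie
    5' of the cut on the forward strand, e.g. HaeIII = GG^CC has site
    ``GGCC`` and offset 2.  The site must be an unambiguous palindrome so
    that a forward-strand scan models both strands.
    """

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.site.upper()
        object.__setattr__(self, "site", site)
        if not site or set(site) - set("ACGT"):
            raise ValueError(
                f"{self.name}: recognition site {self.site!r} contains "
                "ambiguity codes; only unambiguous A/C/G/T sites are supported"
            )
        if _revcomp(site) != site:
            raise ValueError(
                f"{self.name}: site {site} is not palindromic; a forward-strand "
                "scan would miss reverse-strand cuts"
            )
        if not 0 <= self.cut_offset <= len(site):
            raise ValueError(f"{self.name}: cut_offset outside [0, {len(site)}]")


#: Common commercially available blunt-end cutters with 4–6 bp palindromic sites.
ENZYMES: dict[str, RestrictionEnzyme] = {
    e.name: e
    for e in [
        RestrictionEnzyme("HaeIII", "GGCC", 2),
        RestrictionEnzyme("AluI", "AGCT", 2),
        RestrictionEnzyme("RsaI", "GTAC", 2),
        RestrictionEnzyme("DpnI", "GATC", 2),
        RestrictionEnzyme("SspI", "AATATT", 3),
        RestrictionEnzyme("EcoRV", "GATATC", 3),
        RestrictionEnzyme("PvuII", "CAGCTG", 3),
        RestrictionEnzyme("StuI", "AGGCCT", 3),
        RestrictionEnzyme("ScaI", "AGTACT", 3),
        RestrictionEnzyme("SmaI", "CCCGGG", 3),
    ]
}


def load_enzymes(path) -> dict[str, RestrictionEnzyme]:
    """Read an enzyme catalogue TSV with columns name, site, cut_offset."""
    tab = pd.read_csv(path, sep="\t", comment="#")
    return {
        str(r["name"]): RestrictionEnzyme(str(r["name"]), str(r["site"]), int(r["cut_offset"]))
        for _, r in tab.iterrows()
    }


@dataclass
class TargetRegionSet:
    """Size-selected restriction fragments: the predicted sequencing targets."""

    intervals: pd.DataFrame  # chrom, start, end, length (+ n_frac, masked_frac)
    min_len: int
    max_len: int
    genome_bp: int

    @property
    def n_fragments(self) -> int:
        return len(self.intervals)

    @property
    def total_bp(self) -> int:
        return int(self.intervals["length"].sum())

    @property
    def genome_fraction(self) -> float:
        return self.total_bp / self.genome_bp if self.genome_bp else 0.0

    def summary(self) -> dict:
        return {
            "min_len": self.min_len,
            "max_len": self.max_len,
            "n_fragments": self.n_fragments,
            "total_bp": self.total_bp,
            "genome_bp": self.genome_bp,
            "genome_fraction": self.genome_fraction,
        }


def find_sites(seq: str, site: str) -> list[int]:
    """All (possibly overlapping) forward-strand occurrence starts of ``site``.

    Matching is case-insensitive.  The site itself is unambiguous A/C/G/T, so
    a window containing N (or any other non-ACGT code) can never match: runs
    of N are cut-opaque by construction.
    """
    pattern = re.compile("(?=" + re.escape(site) + ")", re.IGNORECASE)
    return [m.start() for m in pattern.finditer(seq)]


def digest(genome: dict[str, str], enzyme: RestrictionEnzyme) -> pd.DataFrame:
    """Digest ``genome`` with ``enzyme``; fragments tile each sequence.

    Every occurrence of the recognition site generates a cut at
    ``start + cut_offset`` (overlapping occurrences all cut; duplicate cut
    positions collapse).  Returns a DataFrame with columns
    ``chrom, start, end, length, n_frac, masked_frac`` where ``n_frac`` is the
    fragment's fraction of N/n bases (assembly gaps are not sequencable
    targets) and ``masked_frac`` its soft-masked (lowercase) fraction, the
    repetitive-content proxy.
    """
    if not genome:
        raise ValueError("empty genome")
    rows: list[tuple] = []
    for chrom, seq in genome.items():
        if not seq:
            raise ValueError(f"sequence {chrom!r} is empty")
        cuts = sorted({p + enzyme.cut_offset for p in find_sites(seq, enzyme.site)})
        bounds = [0] + [c for c in cuts if 0 < c < len(seq)] + [len(seq)]
        for start, end in zip(bounds[:-1], bounds[1:]):
            frag = seq[start:end]
            n_frac = (frag.count("N") + frag.count("n")) / len(frag)
            masked = sum(c.islower() for c in frag) / len(frag)
            rows.append((chrom, start, end, end - start, n_frac, masked))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "length", "n_frac", "masked_frac"]
    )


def _genome_bp(fragments: pd.DataFrame) -> int:
    # fragments tile the genome, so their total length is the genome length
    return int(fragments["length"].sum())


def select_fragments(
    fragments: pd.DataFrame,
    min_len: int,
    max_len: int,
    genome_bp: int | None = None,
) -> TargetRegionSet:
    """Keep fragments with ``min_len <= length <= max_len`` (both inclusive)."""
    if not 1 <= min_len <= max_len:
        raise ValueError(f"invalid length window [{min_len}, {max_len}]")
    keep = fragments[(fragments["length"] >= min_len) & (fragments["length"] <= max_len)]
    return TargetRegionSet(
        intervals=keep.reset_index(drop=True),
        min_len=min_len,
        max_len=max_len,
        genome_bp=genome_bp if genome_bp is not None else _genome_bp(fragments),
    )


def fragment_profile(fragments: pd.DataFrame, max_plot_len: int | None = None) -> pd.DataFrame:
    """Length-distribution table: per fragment length L, the number of
    fragments, ``count * L`` (bp contributed per length class, the quantity an
    electropherogram approximates), and the mean soft-masked fraction."""
    frag = fragments
    if max_plot_len is not None:
        frag = frag[frag["length"] <= max_plot_len]
    if frag.empty:
        return pd.DataFrame(columns=["length", "count", "count_x_length", "masked_frac"])
    grouped = frag.groupby("length")
    out = grouped.size().rename("count").reset_index()
    out["count_x_length"] = out["count"] * out["length"]
    out["masked_frac"] = grouped["masked_frac"].mean().values
    return out


def window_sensitivity(
    fragments: pd.DataFrame,
    base_window: tuple[int, int],
    shifts: list[tuple[int, int]],
    genome_bp: int | None = None,
) -> pd.DataFrame:
    """Compare size-selection windows against a base window.

    Reports, per window, the fragment count, total bp, genome fraction, and
    the relative change in total bp versus the base window — the design
    sensitivity of the sampled genome proportion to the excised size range.
    """
    gbp = genome_bp if genome_bp is not None else _genome_bp(fragments)
    rows = []
    base = select_fragments(fragments, *base_window, genome_bp=gbp)
    for window in [base_window, *shifts]:
        sel = select_fragments(fragments, *window, genome_bp=gbp)
        rel = (sel.total_bp - base.total_bp) / base.total_bp if base.total_bp else float("nan")
        rows.append(
            {
                "min_len": window[0],
                "max_len": window[1],
                "n_fragments": sel.n_fragments,
                "total_bp": sel.total_bp,
                "genome_fraction": sel.genome_fraction,
                "rel_change_vs_base": rel,
            }
        )
    return pd.DataFrame(rows)
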