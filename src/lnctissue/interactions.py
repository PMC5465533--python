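"""Local lncRNA-mRNA interaction sites and pair-level energy aggregates.

A *local interaction site* is an ungapped antisense duplex between a window
of the lncRNA and a window of the mRNA, with a hybridisation energy in
kcal/mol (negative = stable).  Site tables normally come from external
interaction predictors via :func:`read_sites_tsv`; :func:`scan_duplex`
offers a small built-in scanner for synthetic sequences (see its docstring
for what it deliberately does not model).

Sites are aggregated per (lncRNA, mRNA) pair into the two ranking
statistics used throughout the pipeline:

* ``MinEnergy`` -- the single most stable site energy;
* ``SumEnergy`` -- the sum of site energies at or below an energy cutoff
  (default -16 kcal/mol), rewarding pairs with several strong sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .errors import ParseError, UsageError, ValidationError

__all__ = [
    "DEFAULT_CUTOFF_KCAL",
    "DEFAULT_PAIR_ENERGIES",
    "DEFAULT_INITIATION_KCAL",
    "LocalInteractionSite",
    "PairScore",
    "read_sites_tsv",
    "write_sites_tsv",
    "read_fasta",
    "scan_duplex",
    "min_energy",
    "sum_energy",
    "score_pairs",
    "write_pair_scores_tsv",
]

#: SumEnergy only counts sites at or below this energy (kcal/mol).
DEFAULT_CUTOFF_KCAL = -16.0

#: Per-base-pair stacking terms of the toy duplex model (kcal/mol).
DEFAULT_PAIR_ENERGIES: Mapping[str, float] = {"GC": -2.2, "AU": -1.1, "GU": -0.6}

#: Duplex initiation penalty added once per site (kcal/mol).
DEFAULT_INITIATION_KCAL = 4.1

_SITE_COLUMNS = (
    "lncrna_id",
    "mrna_id",
    "lnc_start",
    "lnc_end",
    "mrna_start",
    "mrna_end",
    "energy_kcal",
)


@dataclass(frozen=True)
class LocalInteractionSite:
    """One ungapped antisense duplex window.

    Coordinates are 1-based inclusive on the sense strand of each
    transcript; the interaction is antisense by construction, so no strand
    field is stored.
    """

    lncrna_id: str
    mrna_id: str
    lnc_start: int
    lnc_end: int
    mrna_start: int
    mrna_end: int
    energy_kcal: float

    def __post_init__(self) -> None:
        if self.lnc_start > self.lnc_end:
            raise ValidationError(
                f"site {self.lncrna_id}/{self.mrna_id}: lnc_start "
                f"{self.lnc_start} > lnc_end {self.lnc_end}"
            )
        if self.mrna_start > self.mrna_end:
            raise ValidationError(
                f"site {self.lncrna_id}/{self.mrna_id}: mrna_start "
                f"{self.mrna_start} > mrna_end {self.mrna_end}"
            )
        if not math.isfinite(self.energy_kcal):
            raise ValidationError(
                f"site {self.lncrna_id}/{self.mrna_id}: non-finite energy"
            )


@dataclass(frozen=True)
class PairScore:
    """MinEnergy / SumEnergy aggregates for one lncRNA-mRNA pair.

    ``min_energy_kcal`` is +inf for a pair without sites.  ``sum_energy_kcal``
    is 0 when no site passes the cutoff; such pairs sort after every pair
    with at least one qualifying site.
    """

    lncrna_id: str
    mrna_id: str
    min_energy_kcal: float
    sum_energy_kcal: float
    n_sites: int
    n_sites_below_cutoff: int


def read_sites_tsv(path: str | Path) -> list[LocalInteractionSite]:
    """Read a 7-column site table (header required, columns as written)."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
        cols = tuple(header.rstrip("\n").rstrip("\r").split("\t"))
        if cols != _SITE_COLUMNS:
            raise ParseError(
                f"{path}, line 1: expected header {list(_SITE_COLUMNS)}, got {list(cols)}"
            )
        sites = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").rstrip("\r").split("\t")
            if len(parts) != 7:
                raise ParseError(
                    f"{path}, line {lineno}: expected 7 columns, found {len(parts)}"
                )
            try:
                coords = [int(v) for v in parts[2:6]]
            except ValueError:
                raise ParseError(
                    f"{path}, line {lineno}: non-integer coordinate"
                ) from None
            try:
                energy = float(parts[6])
            except ValueError:
                raise ParseError(
                    f"{path}, line {lineno}: non-numeric energy {parts[6]!r}"
                ) from None
            try:
                sites.append(
                    LocalInteractionSite(parts[0], parts[1], *coords, energy)
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}, line {lineno}: {exc}") from None
    return sites


def write_sites_tsv(sites: Iterable[LocalInteractionSite], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_SITE_COLUMNS) + "\n")
        for s in sites:
            fh.write(
                f"{s.lncrna_id}\t{s.mrna_id}\t{s.lnc_start}\t{s.lnc_end}\t"
                f"{s.mrna_start}\t{s.mrna_end}\t{s.energy_kcal!r}\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences from FASTA; IDs are taken up to the first whitespace."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


_WOBBLE_PAIRS = {
    frozenset(("G", "C")): "GC",
    frozenset(("A", "U")): "AU",
    frozenset(("G", "U")): "GU",
}


def _clean_rna(seq: str, name: str, min_len: int) -> str:
    s = seq.upper().replace("T", "U")
    bad = sorted(set(s) - set("ACGU"))
    if bad:
        raise UsageError(f"{name}: invalid RNA characters {bad}")
    if len(s) < min_len:
        raise UsageError(f"{name}: length {len(s)} < min_len {min_len}")
    return s


def scan_duplex(
    lnc_seq: str,
    mrna_seq: str,
    min_len: int = 8,
    pair_energies: Mapping[str, float] | None = None,
    initiation_kcal: float = DEFAULT_INITIATION_KCAL,
    lncrna_id: str = "lncRNA",
    mrna_id: str = "mRNA",
) -> list[LocalInteractionSite]:
    """Find all maximal ungapped antisense complementary stretches.

    Complementarity is Watson-Crick (A:U, G:C) plus the G:U wobble.  The two
    strands run antiparallel, so a stretch pairs lncRNA positions
    i..i+k-1 with mRNA positions j..j+k-1 read in the opposite direction:
    consecutive pairings lie on one anti-diagonal of the complementarity
    matrix.  Site energy is the sum of per-base-pair terms (defaults
    GC -2.2, AU -1.1, GU -0.6 kcal/mol) plus one initiation penalty
    (+4.1 kcal/mol).  Shorter stretches contained in a maximal stretch are
    not reported.

    This is a deliberately *non-thermodynamic* toy model: no accessibility,
    mismatch, or loop terms.  Real analyses should supply site tables from a
    dedicated RNA-RNA interaction predictor via :func:`read_sites_tsv`.
    ``T`` is accepted in input and read as ``U``.
    """
    a = _clean_rna(lnc_seq, "lnc_seq", min_len)
    b = _clean_rna(mrna_seq, "mrna_seq", min_len)
    energies = dict(DEFAULT_PAIR_ENERGIES)
    if pair_energies:
        energies.update(pair_energies)
    n, m = len(a), len(b)
    sites: list[LocalInteractionSite] = []
    for diag in range(n + m - 1):
        i_lo = max(0, diag - m + 1)
        i_hi = min(n - 1, diag)
        run_start = None
        run_energy = 0.0
        for i in range(i_lo, i_hi + 2):
            key = None
            if i <= i_hi:
                key = _WOBBLE_PAIRS.get(frozenset((a[i], b[diag - i])))
            if key is not None:
                if run_start is None:
                    run_start = i
                    run_energy = 0.0
                run_energy += energies[key]
            else:
                if run_start is not None and i - run_start >= min_len:
                    i_end = i - 1
                    sites.append(
                        LocalInteractionSite(
                            lncrna_id,
                            mrna_id,
                            run_start + 1,
                            i_end + 1,
                            diag - i_end + 1,
                            diag - run_start + 1,
                            run_energy + initiation_kcal,
                        )
                    )
                run_start = None
    return sites


def _single_pair(sites: Sequence[LocalInteractionSite], op: str) -> None:
    ids = {(s.lncrna_id, s.mrna_id) for s in sites}
    if len(ids) > 1:
        raise UsageError(f"{op}: sites span multiple pairs: {sorted(ids)[:3]}")


def min_energy(sites: Sequence[LocalInteractionSite]) -> float:
    """Most stable site energy for one pair; +inf for an empty site list."""
    _single_pair(sites, "min_energy")
    if not sites:
        return math.inf
    return min(s.energy_kcal for s in sites)


def sum_energy(
    sites: Sequence[LocalInteractionSite],
    cutoff_kcal: float = DEFAULT_CUTOFF_KCAL,
) -> float:
    """Sum of site energies at or below the cutoff (inclusive); 0 if none."""
    _single_pair(sites, "sum_energy")
    return float(sum(s.energy_kcal for s in sites if s.energy_kcal <= cutoff_kcal))


def score_pairs(
    sites: Iterable[LocalInteractionSite],
    cutoff_kcal: float = DEFAULT_CUTOFF_KCAL,
) -> list[PairScore]:
    """Aggregate a site list into one :class:`PairScore` per pair.

    Output is sorted by (lncrna_id, mrna_id) for reproducibility.
    """
    groups: dict[tuple[str, str], list[LocalInteractionSite]] = {}
    for s in sites:
        groups.setdefault((s.lncrna_id, s.mrna_id), []).append(s)
    scores = []
    for (lnc, mrna) in sorted(groups):
        grp = groups[(lnc, mrna)]
        qualifying = [s for s in grp if s.energy_kcal <= cutoff_kcal]
        scores.append(
            PairScore(
                lncrna_id=lnc,
                mrna_id=mrna,
                min_energy_kcal=min(s.energy_kcal for s in grp),
                sum_energy_kcal=float(sum(s.energy_kcal for s in qualifying)),
                n_sites=len(grp),
                n_sites_below_cutoff=len(qualifying),
            )
        )
    return scores


def write_pair_scores_tsv(scores: Iterable[PairScore], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(
            "lncrna_id\tmrna_id\tmin_energy_kcal\tsum_energy_kcal\t"
            "n_sites\tn_sites_below_cutoff\n"
        )
        for s in scores:
            fh.write(
                f"{s.lncrna_id}\t{s.mrna_id}\t{s.min_energy_kcal!r}\t"
                f"{s.sum_energy_kcal!r}\t{s.n_sites}\t{s.n_sites_below_cutoff}\n"
            )
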