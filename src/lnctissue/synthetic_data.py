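"""Seeded synthetic benchmark generator.

Generates expression matrices, gene catalogs, interaction-site tables and a
validated-target list with the statistical structure the pipeline assumes
of real multi-tissue RNA-seq plus interaction-database inputs:

* a bimodal tissue-specificity landscape -- most lncRNAs either ubiquitous
  (score near 0) or confined to one tissue (score near log2 N), with
  lncRNAs far more often specific than protein-coding genes;
* one focal lncRNA planted specific to a small set of tissues (the TINCR
  pattern: an epidermal-differentiation lncRNA specific to skin and a
  couple of related tissues);
* true-interactor mRNAs concentrated among mRNAs specific to the focal
  lncRNA's tissue(s);
* local interaction-site energies stochastically lower (more negative) for
  true interactors than for the rest, with many pairs carrying no detected
  site at all, as in sparse interaction-site databases.

Ubiquitous genes draw log2(FPKM+1) i.i.d. per tissue from a Normal
baseline.  Specific genes are *silent* outside their planted tissues
(|Normal(0, silent_log_sd)|, i.e. FPKM ~ 0) and elevated
(baseline + specific_boost) inside them -- silence off-tissue is what puts
single-tissue genes at the maximum of the specificity-score range, exactly
as real tissue-restricted transcripts behave.

All randomness flows from one seeded generator; identical configs produce
byte-identical benchmark files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expression_io import ExpressionMatrix, GeneCatalog, write_expression_tsv, write_gene_catalog_tsv
from .interactions import LocalInteractionSite, write_sites_tsv

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_expression",
    "simulate_sites",
    "write_benchmark",
]

#: Probability that a planted-specific gene covers 1, 2 or 3 tissues.
PLANTED_TISSUE_COUNT_PROBS = (0.7, 0.2, 0.1)

#: Transcript length assumed for the focal lncRNA when placing sites (nt).
FOCAL_LNC_LENGTH = 3000

_MRNA_LENGTH_RANGE = (500, 5000)
_SITE_LENGTH_RANGE = (10, 25)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic benchmark.

    ``baseline_log_expr`` is the (mean, sd) of log2(FPKM+1) for expressed
    tissues; ``specific_boost`` the additional log2 elevation in planted
    tissues; ``silent_log_sd`` the near-zero spread of specific genes
    outside their tissues.  ``energy_true`` / ``energy_false`` are (mean,
    sd) of per-site energies (kcal/mol) for true-interactor vs other pairs.
    ``sites_per_pair`` is an inclusive integer range for the number of
    local sites detected per (focal lncRNA, mRNA) pair; the default (0, 1)
    leaves about half of all pairs without any detected site.
    ``enrichment_factor`` e concentrates the validated targets: a fraction
    1 - 1/e of them is planted specific to the focal tissue(s), the rest
    follow the background law.
    """

    n_tissues: int = 16
    n_lncrna: int = 300
    n_mrna: int = 700
    frac_specific_lnc: float = 0.8
    frac_specific_mrna: float = 0.5
    focal_tissues: tuple[str, ...] | None = None
    n_true_interactors: int = 40
    enrichment_factor: float = 4.0
    baseline_log_expr: tuple[float, float] = (5.0, 0.5)
    specific_boost: float = 5.0
    silent_log_sd: float = 0.02
    energy_true: tuple[float, float] = (-22.0, 3.0)
    energy_false: tuple[float, float] = (-12.0, 3.0)
    sites_per_pair: tuple[int, int] = (0, 1)
    seed: int = 1

    @property
    def tissue_names(self) -> list[str]:
        return [f"tissue{i + 1:02d}" for i in range(self.n_tissues)]

    @property
    def focal(self) -> tuple[str, ...]:
        if self.focal_tissues is not None:
            return tuple(self.focal_tissues)
        return (self.tissue_names[0],)

    @property
    def focal_lncrna_id(self) -> str:
        return "LNC0001"

    def validate(self) -> None:
        """Raise :class:`ValidationError` naming the first offending field."""
        if self.n_tissues < 4:
            raise ValidationError(f"n_tissues must be >= 4, got {self.n_tissues}")
        for name in ("n_lncrna", "n_mrna", "n_true_interactors"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("frac_specific_lnc", "frac_specific_mrna"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.enrichment_factor < 1.0:
            raise ValidationError(
                f"enrichment_factor must be >= 1, got {self.enrichment_factor}"
            )
        if self.n_true_interactors > self.n_mrna:
            raise ValidationError(
                f"n_true_interactors ({self.n_true_interactors}) exceeds "
                f"n_mrna ({self.n_mrna})"
            )
        lo, hi = self.sites_per_pair
        if lo < 0 or hi < lo:
            raise ValidationError(
                f"sites_per_pair must be a non-negative range, got {self.sites_per_pair}"
            )
        unknown = set(self.focal) - set(self.tissue_names)
        if unknown:
            raise ValidationError(
                f"focal_tissues not among generated tissues: {sorted(unknown)}"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        """Rebuild a config from a manifest dictionary (lists -> tuples)."""
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            if isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
        return cls(**kwargs)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted.

    ``planted_tissues`` maps every gene ID to the tuple of tissues it was
    made specific to (empty tuple = ubiquitous).
    """

    focal_lncrna_id: str
    true_interactor_ids: frozenset[str]
    planted_tissues: dict[str, tuple[str, ...]]

    def planted_specific(self, gene_id: str) -> bool:
        return bool(self.planted_tissues.get(gene_id, ()))


def _rng_for(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams for expression / sites / sequences
    return np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[stream])


def _plant_tissues(rng: np.random.Generator, tissues: list[str]) -> tuple[str, ...]:
    k = int(rng.choice((1, 2, 3), p=PLANTED_TISSUE_COUNT_PROBS))
    idx = rng.choice(len(tissues), size=k, replace=False)
    return tuple(tissues[i] for i in sorted(idx))


def simulate_expression(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, GeneCatalog, GroundTruth]:
    """Generate the raw FPKM matrix, gene catalog and planted ground truth."""
    cfg.validate()
    rng = _rng_for(cfg, 0)
    tissues = cfg.tissue_names
    lnc_ids = [f"LNC{i + 1:04d}" for i in range(cfg.n_lncrna)]
    mrna_ids = [f"MRNA{i + 1:04d}" for i in range(cfg.n_mrna)]

    planted: dict[str, tuple[str, ...]] = {}

    # lncRNAs: the focal lncRNA is the first of the specific ones, planted
    # to the focal tissues; with frac_specific_lnc == 0 nothing is specific.
    n_spec_lnc = round(cfg.frac_specific_lnc * cfg.n_lncrna)
    spec_lnc = set(lnc_ids[:n_spec_lnc])
    for gid in lnc_ids:
        if gid not in spec_lnc:
            planted[gid] = ()
        elif gid == cfg.focal_lncrna_id:
            planted[gid] = cfg.focal
        else:
            planted[gid] = _plant_tissues(rng, tissues)

    # mRNAs: background specificity first ...
    n_spec_mrna = round(cfg.frac_specific_mrna * cfg.n_mrna)
    spec_mrna_idx = set(rng.choice(cfg.n_mrna, size=n_spec_mrna, replace=False).tolist())
    for i, gid in enumerate(mrna_ids):
        planted[gid] = _plant_tissues(rng, tissues) if i in spec_mrna_idx else ()

    # ... then the validated-target set, concentrated in the focal tissues:
    # a fraction 1 - 1/enrichment_factor of true interactors is re-planted
    # focal-specific, the rest keep their background assignment.
    true_idx = rng.choice(cfg.n_mrna, size=cfg.n_true_interactors, replace=False)
    true_ids = [mrna_ids[i] for i in sorted(true_idx.tolist())]
    p_forced = 1.0 - 1.0 / cfg.enrichment_factor
    for gid in true_ids:
        if rng.random() < p_forced:
            planted[gid] = cfg.focal

    mean, sd = cfg.baseline_log_expr
    gene_ids = lnc_ids + mrna_ids
    log_expr = np.empty((len(gene_ids), cfg.n_tissues))
    t_index = {t: j for j, t in enumerate(tissues)}
    for i, gid in enumerate(gene_ids):
        where = planted[gid]
        if not where:
            log_expr[i] = np.clip(rng.normal(mean, sd, cfg.n_tissues), 0.0, None)
        else:
            row = np.abs(rng.normal(0.0, cfg.silent_log_sd, cfg.n_tissues))
            for t in where:
                row[t_index[t]] = max(
                    rng.normal(mean + cfg.specific_boost, sd), 0.0
                )
            log_expr[i] = row

    fpkm = np.clip(np.exp2(log_expr) - 1.0, 0.0, None)
    df = pd.DataFrame(fpkm, index=gene_ids, columns=tissues)
    df.index.name = "gene_id"
    matrix = ExpressionMatrix(df, transformed=False)
    catalog = GeneCatalog(
        {**{g: "lncRNA" for g in lnc_ids}, **{g: "protein_coding" for g in mrna_ids}}
    )
    truth = GroundTruth(
        focal_lncrna_id=cfg.focal_lncrna_id,
        true_interactor_ids=frozenset(true_ids),
        planted_tissues=planted,
    )
    return matrix, catalog, truth


def simulate_sites(
    cfg: SimulationConfig, truth: GroundTruth
) -> list[LocalInteractionSite]:
    """Generate local interaction sites between the focal lncRNA and each mRNA.

    Per pair, a site count is drawn uniformly from the inclusive
    ``sites_per_pair`` range; site energies come from ``energy_true`` for
    validated interactors and ``energy_false`` otherwise; coordinates are
    uniform within plausible transcript lengths.  Deterministic given the
    config seed.
    """
    cfg.validate()
    rng = _rng_for(cfg, 1)
    lo, hi = cfg.sites_per_pair
    mrna_ids = sorted(
        g for g, t in truth.planted_tissues.items() if g.startswith("MRNA")
    )
    sites: list[LocalInteractionSite] = []
    for mrna in mrna_ids:
        n_sites = int(rng.integers(lo, hi + 1))
        mrna_len = int(rng.integers(*_MRNA_LENGTH_RANGE))
        mu, sd = (
            cfg.energy_true
            if mrna in truth.true_interactor_ids
            else cfg.energy_false
        )
        for _ in range(n_sites):
            w = int(rng.integers(_SITE_LENGTH_RANGE[0], _SITE_LENGTH_RANGE[1] + 1))
            ls = int(rng.integers(1, FOCAL_LNC_LENGTH - w + 1))
            ms = int(rng.integers(1, max(mrna_len - w, 1) + 1))
            sites.append(
                LocalInteractionSite(
                    lncrna_id=truth.focal_lncrna_id,
                    mrna_id=mrna,
                    lnc_start=ls,
                    lnc_end=ls + w - 1,
                    mrna_start=ms,
                    mrna_end=ms + w - 1,
                    energy_kcal=float(rng.normal(mu, sd)),
                )
            )
    return sites


_RC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _demo_sequences(cfg: SimulationConfig, truth: GroundTruth) -> dict[str, str]:
    """Small FASTA payload: focal lncRNA plus three mRNAs, each carrying a
    20-nt antisense-complementary window for duplex-scanner demos."""
    rng = _rng_for(cfg, 2)
    bases = np.array(list("ACGU"))
    lnc = "".join(rng.choice(bases, size=600))
    window = lnc[100:120]
    antisense = "".join(_RC[b] for b in reversed(window))
    seqs = {truth.focal_lncrna_id: lnc}
    for mrna in sorted(truth.true_interactor_ids)[:3]:
        body = "".join(rng.choice(bases, size=400))
        pos = int(rng.integers(50, 330))
        seqs[mrna] = body[:pos] + antisense + body[pos + len(antisense):]
    return seqs


def _write_fasta(seqs: dict[str, str], path: Path, width: int = 60) -> None:
    with path.open("w", encoding="utf-8") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_benchmark(cfg: SimulationConfig, out_dir: str | Path) -> dict:
    """Write a complete benchmark directory and return its manifest.

    Files: expression.tsv, catalog.tsv, sites.tsv, truth.txt,
    sequences.fasta and manifest.json -- all in the formats the I/O modules
    read back, and byte-identical when regenerated from the same config.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, catalog, truth = simulate_expression(cfg)
    sites = simulate_sites(cfg, truth)

    write_expression_tsv(matrix, out / "expression.tsv")
    write_gene_catalog_tsv(catalog, out / "catalog.tsv")
    write_sites_tsv(sites, out / "sites.tsv")
    with (out / "truth.txt").open("w", encoding="utf-8") as fh:
        for gid in sorted(truth.true_interactor_ids):
            fh.write(gid + "\n")
    _write_fasta(_demo_sequences(cfg, truth), out / "sequences.fasta")

    manifest = {
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "focal_lncrna_id": truth.focal_lncrna_id,
        "files": {
            "expression": "expression.tsv",
            "catalog": "catalog.tsv",
            "sites": "sites.tsv",
            "truth": "truth.txt",
            "sequences": "sequences.fasta",
        },
    }
    with (out / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
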