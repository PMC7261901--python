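"""Seeded synthetic two-group RNA-seq studies with planted structure.

Generates count matrices for three feature classes (mRNA, lncRNA, miRNA)
under a negative-binomial model (variance = mu + dispersion * mu**2), with
optionally planted

* differentially expressed features (fixed log2 fold-change shifts),
* co-expressed modules driven by latent per-sample factors, and
* sponge triples (lncRNA, miRNA, mRNA) in which a shared latent "miRNA
  activity" raises the miRNA and lowers its two targets, so the targets
  co-vary positively and all three members are differentially expressed.

Every triple is accompanied by ``partners_per_triple`` extra miRNAs driven
by the same activity and targeting the same lncRNA/mRNA pair, so that a
planted pair shares more than one miRNA and can survive a strict
shared-miRNA bound downstream.

All randomness flows through one ``numpy`` Generator seeded from the
config, so identical configs reproduce identical studies bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

CONTROL = "control"
CONDITION = "condition"

_CLASS_PREFIX = {"mrna": "mRNA", "lncrna": "lnc", "mirna": "miR"}

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ExpressionStudy",
    "simulate_study",
    "simulate_target_table",
    "write_fixture",
]


class ConfigurationError(ValueError):
    """Raised when a simulation config is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study generator.

    ``base_mean_log2_range`` bounds the per-feature baseline expression on
    the log2 scale; ``library_size_range`` bounds per-sample scaling.
    """

    n_mrna: int = 300
    n_lncrna: int = 100
    n_mirna: int = 60
    n_per_group: int = 10
    base_mean_log2_range: tuple[float, float] = (6.0, 10.0)
    dispersion: float = 0.05
    de_fraction: float = 0.1
    de_log2fc: float = 1.5
    n_modules: int = 0
    module_size: int = 20
    module_strength: float = 0.8
    n_cerna_triples: int = 0
    sponge_strength: float = 0.9
    partners_per_triple: int = 1
    decoy_target_fraction: float = 0.0
    library_size_range: tuple[float, float] = (0.7, 1.3)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mrna", "n_lncrna", "n_mirna", "n_modules",
                     "module_size", "n_cerna_triples", "partners_per_triple"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_per_group < 3:
            raise ConfigurationError("n_per_group must be >= 3")
        if not 0 < self.module_strength <= 1:
            raise ConfigurationError("module_strength must be in (0, 1]")
        if not 0 < self.sponge_strength <= 1:
            raise ConfigurationError("sponge_strength must be in (0, 1]")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        if not 0 <= self.de_fraction <= 1:
            raise ConfigurationError("de_fraction must be in [0, 1]")
        if not 0 <= self.decoy_target_fraction < 1:
            raise ConfigurationError("decoy_target_fraction must be in [0, 1)")
        lo, hi = self.base_mean_log2_range
        if not lo <= hi:
            raise ConfigurationError("base_mean_log2_range must be ordered")
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise ConfigurationError("library_size_range must be positive and ordered")

    def feature_ids(self, feature_class: str) -> list[str]:
        """Deterministic feature identifiers of one class."""
        prefix = _CLASS_PREFIX[feature_class]
        n = {"mrna": self.n_mrna, "lncrna": self.n_lncrna,
             "mirna": self.n_mirna}[feature_class]
        return [f"{prefix}_{i + 1:04d}" for i in range(n)]

    def sample_ids(self) -> list[str]:
        n = self.n_per_group
        return ([f"ctrl_{i + 1:02d}" for i in range(n)]
                + [f"cond_{i + 1:02d}" for i in range(n)])


@dataclass
class GroundTruth:
    """What was planted: DE features, modules, triples and true target edges."""

    de_features: set[tuple[str, str]] = field(default_factory=set)
    module_membership: dict[str, str] = field(default_factory=dict)
    cerna_triples: list[tuple[str, str, str]] = field(default_factory=list)
    true_target_edges: set[tuple[str, str]] = field(default_factory=set)

    def validate(self) -> None:
        for _, direction in self.de_features:
            if direction not in ("up", "down"):
                raise ValueError(f"bad DE direction {direction!r}")
        for lnc, mir, mrna in self.cerna_triples:
            for target in (lnc, mrna):
                if (mir, target) not in self.true_target_edges:
                    raise ValueError(
                        f"triple edge ({mir}, {target}) missing from true_target_edges")


@dataclass
class ExpressionStudy:
    """Count matrices (features x samples) per class plus the sample sheet."""

    counts: dict[str, pd.DataFrame]
    sample_sheet: pd.DataFrame  # columns: sample, group
    truth: Optional[GroundTruth] = None

    def __post_init__(self) -> None:
        cols = None
        for cls, mat in self.counts.items():
            if cols is None:
                cols = list(mat.columns)
            elif list(mat.columns) != cols:
                raise ValueError(f"sample columns of {cls} differ from other classes")
            values = mat.to_numpy()
            if values.size and (not np.issubdtype(values.dtype, np.integer)
                                or (values < 0).any()):
                raise ValueError(f"{cls} counts must be non-negative integers")
        groups = set(self.sample_sheet["group"])
        if not {CONTROL, CONDITION} <= groups:
            raise ValueError("sample sheet must contain both groups")
        if cols is not None and list(self.sample_sheet["sample"]) != cols:
            raise ValueError("sample sheet order must match count columns")
        if self.truth is not None:
            self.truth.validate()

    def samples_of(self, group: str) -> list[str]:
        sheet = self.sample_sheet
        return list(sheet.loc[sheet["group"] == group, "sample"])


def _pick(rng: np.random.Generator, pool: list[str], k: int, what: str) -> list[str]:
    if k > len(pool):
        raise ConfigurationError(f"not enough features to plant {what} "
                                 f"({k} needed, {len(pool)} available)")
    chosen = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in sorted(chosen)]


def simulate_study(config: SimulationConfig) -> ExpressionStudy:
    """Draw a complete study (counts + truth) for one config.

    Log2-scale latent means are assembled as
    baseline + group-shift (planted DE) + module loadings + sponge terms,
    then counts are drawn NB with the configured dispersion and scaled by
    per-sample library sizes.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    samples = cfg.sample_ids()
    n_samples = len(samples)
    cond = np.array([0.0] * cfg.n_per_group + [1.0] * cfg.n_per_group)

    ids = {cls: cfg.feature_ids(cls) for cls in ("mrna", "lncrna", "mirna")}
    lo, hi = cfg.base_mean_log2_range
    base = {cls: rng.uniform(lo, hi, size=(len(ids[cls]), 1)) for cls in ids}
    effect = {cls: np.zeros((len(ids[cls]), n_samples)) for cls in ids}
    truth = GroundTruth()

    # --- sponge triples -------------------------------------------------
    n_trip = cfg.n_cerna_triples
    trip_lnc = _pick(rng, ids["lncrna"], n_trip, "triple lncRNAs")
    trip_mrna = _pick(rng, ids["mrna"], n_trip, "triple mRNAs")
    n_mir_needed = n_trip * (1 + cfg.partners_per_triple)
    trip_mirs = _pick(rng, ids["mirna"], n_mir_needed, "triple miRNAs")
    primary = trip_mirs[:n_trip]
    partners = [trip_mirs[n_trip + t * cfg.partners_per_triple:
                          n_trip + (t + 1) * cfg.partners_per_triple]
                for t in range(n_trip)]
    # shift the activity mean so the induced log2FC equals de_log2fc
    delta = cfg.de_log2fc / cfg.sponge_strength
    row = {cls: {fid: i for i, fid in enumerate(ids[cls])} for cls in ids}
    for t in range(n_trip):
        activity = rng.normal(0.0, 1.0, size=n_samples) + delta * cond
        lnc, mrna = trip_lnc[t], trip_mrna[t]
        mirs = [primary[t], *partners[t]]
        for mir in mirs:
            effect["mirna"][row["mirna"][mir]] += cfg.sponge_strength * activity
            truth.de_features.add((mir, "up"))
            truth.true_target_edges.add((mir, lnc))
            truth.true_target_edges.add((mir, mrna))
        effect["lncrna"][row["lncrna"][lnc]] -= cfg.sponge_strength * activity
        effect["mrna"][row["mrna"][mrna]] -= cfg.sponge_strength * activity
        truth.de_features.add((lnc, "down"))
        truth.de_features.add((mrna, "down"))
        truth.cerna_triples.append((lnc, primary[t], mrna))

    reserved = set(trip_lnc) | set(trip_mrna) | set(trip_mirs)

    # --- planted DE (outside triples) -----------------------------------
    for cls in ("mrna", "lncrna", "mirna"):
        pool = [f for f in ids[cls] if f not in reserved]
        n_de = int(round(cfg.de_fraction * len(ids[cls])))
        chosen = _pick(rng, pool, min(n_de, len(pool)), f"DE {cls}")
        signs = rng.choice([1.0, -1.0], size=len(chosen))
        for fid, sign in zip(chosen, signs):
            effect[cls][row[cls][fid]] += sign * cfg.de_log2fc * cond
            truth.de_features.add((fid, "up" if sign > 0 else "down"))

    # --- co-expression modules (lncRNA + mRNA, outside triples) ---------
    module_pool = ([f for f in ids["mrna"] if f not in reserved]
                   + [f for f in ids["lncrna"] if f not in reserved])
    need = cfg.n_modules * cfg.module_size
    if need > len(module_pool):
        raise ConfigurationError(
            f"n_modules * module_size = {need} exceeds available features "
            f"({len(module_pool)})")
    members = _pick(rng, module_pool, need, "modules")
    for m in range(cfg.n_modules):
        factor = rng.normal(0.0, 1.0, size=n_samples)
        for fid in members[m * cfg.module_size:(m + 1) * cfg.module_size]:
            cls = "mrna" if fid.startswith(_CLASS_PREFIX["mrna"]) else "lncrna"
            effect[cls][row[cls][fid]] += cfg.module_strength * factor
            truth.module_membership[fid] = f"M{m + 1}"

    # --- counts ---------------------------------------------------------
    libsize = rng.uniform(*cfg.library_size_range, size=n_samples)
    counts: dict[str, pd.DataFrame] = {}
    r = 1.0 / cfg.dispersion
    for cls in ("mrna", "lncrna", "mirna"):
        mu = libsize[None, :] * np.exp2(base[cls] + effect[cls])
        if mu.size:
            p = r / (r + mu)
            drawn = rng.negative_binomial(r, p)
        else:
            drawn = np.zeros_like(mu, dtype=np.int64)
        counts[cls] = pd.DataFrame(drawn.astype(np.int64),
                                   index=ids[cls], columns=samples)

    sheet = pd.DataFrame({
        "sample": samples,
        "group": [CONTROL] * cfg.n_per_group + [CONDITION] * cfg.n_per_group,
    })
    return ExpressionStudy(counts=counts, sample_sheet=sheet, truth=truth)


def simulate_target_table(truth: GroundTruth, config: SimulationConfig) -> pd.DataFrame:
    """miRNA->target table: all true edges plus random decoy edges.

    Columns: mirna, target, target_class, mre_count. The decoy count is set
    so decoys make up ``decoy_target_fraction`` of the final table. Uses an
    RNG stream derived from (seed, 7), independent of the study draws.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 7])
    true_edges = sorted(truth.true_target_edges)
    f = cfg.decoy_target_fraction
    n_decoy = int(round(f / (1.0 - f) * len(true_edges))) if f > 0 else 0

    mirnas = cfg.feature_ids("mirna")
    candidates = cfg.feature_ids("mrna") + cfg.feature_ids("lncrna")
    decoys: list[tuple[str, str]] = []
    taken = set(true_edges)
    attempts = 0
    while len(decoys) < n_decoy:
        attempts += 1
        if attempts > 100 * max(n_decoy, 1) + 1000:
            raise ConfigurationError("cannot place requested decoy edges")
        mir = mirnas[rng.integers(len(mirnas))]
        tgt = candidates[rng.integers(len(candidates))]
        if (mir, tgt) in taken:
            continue
        taken.add((mir, tgt))
        decoys.append((mir, tgt))

    rows = []
    for mir, tgt in true_edges + sorted(decoys):
        cls = "mRNA" if tgt.startswith(_CLASS_PREFIX["mrna"]) else "lncRNA"
        rows.append((mir, tgt, cls, int(rng.integers(1, 4))))
    return pd.DataFrame(rows, columns=["mirna", "target", "target_class", "mre_count"])


def write_fixture(study: ExpressionStudy, directory: str | Path,
                  targets: Optional[pd.DataFrame] = None) -> dict[str, Path]:
    """Write the study (and optional target table) as plain TSV/JSON files.

    Emits mrna_counts.tsv / lncrna_counts.tsv / mirna_counts.tsv,
    samples.tsv, optionally targets.tsv and truth.json; the io module
    round-trips all of them.
    """
    from . import io as cio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for cls, mat in study.counts.items():
        path = directory / f"{cls}_counts.tsv"
        cio.write_counts(mat, path)
        written[cls] = path
    path = directory / "samples.tsv"
    cio.write_sample_sheet(study.sample_sheet, path)
    written["samples"] = path
    if targets is not None:
        path = directory / "targets.tsv"
        cio.write_target_table(targets, path)
        written["targets"] = path
    if study.truth is not None:
        path = directory / "truth.json"
        cio.write_truth(study.truth, path)
        written["truth"] = path
    return written
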