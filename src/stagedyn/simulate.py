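"""Synthetic staged RNA-seq count data with planted truth.

Emulates the four-stage tumor-progression design (weeks 6/8/10/12, tumor vs
age-matched control, three replicates per cell): negative-binomial counts with
per-gene dispersion, library-size variation, stage-constant and
stage-progressive differential expression, genes with designated inter-stage
transition patterns, and latent-factor co-expression modules whose factor can
track tumor stage.  Every gene carries a truth record so downstream stages are
testable offline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

STAGE_WEEKS = (6, 8, 10, 12)
LFC_COLUMNS = ["lfc_w6", "lfc_w8", "lfc_w10", "lfc_w12"]


class InvalidConfigError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic staged count simulation.

    Effect sizes are in log2 units.  Baseline per-gene mean counts are
    log-normal with natural-log location/scale ``baseline_log_mean_loc`` /
    ``baseline_log_mean_scale``; per-gene NB dispersions are log-normal around
    ``dispersion_median``.  Fractions of planted gene classes plus module
    members must leave a non-negative remainder of null genes.
    """

    n_genes: int = 5000
    weeks: Sequence[int] = STAGE_WEEKS
    n_replicates: int = 3
    baseline_log_mean_loc: float = 4.0
    baseline_log_mean_scale: float = 1.5
    dispersion_median: float = 0.1
    dispersion_log_sd: float = 0.5
    library_size_sigma: float = 0.15
    library_size_factors: Sequence[float] | None = None
    frac_constant_deg: float = 0.05
    frac_progressive_deg: float = 0.02
    frac_transition: float = 0.02
    constant_deg_lfc: float = 3.0
    progressive_deg_lfc_max: float = 3.0
    transition_lfc: float = 3.0
    n_modules: int = 2
    module_size: int = 50
    n_stage_modules: int = 1
    module_loading_scale: float = 1.0
    module_factor_noise_sd: float = 1.0
    litter_effect_sd: float = 0.1
    batch_effect_sd: float = 0.1
    n_litters: int = 4
    n_batches: int = 2
    rng_seed: int = 0

    @property
    def n_samples(self) -> int:
        return 2 * len(self.weeks) * self.n_replicates

    def n_planted(self) -> dict[str, int]:
        n = self.n_genes
        return {
            "constant_deg": int(round(self.frac_constant_deg * n)),
            "progressive_deg": int(round(self.frac_progressive_deg * n)),
            "transition": int(round(self.frac_transition * n)),
            "module": self.n_modules * self.module_size,
        }

    def validate(self) -> None:
        if self.n_genes < 1:
            raise InvalidConfigError("n_genes must be positive")
        if self.n_replicates < 2:
            raise InvalidConfigError("need at least 2 replicates per design cell")
        fracs = (self.frac_constant_deg, self.frac_progressive_deg, self.frac_transition)
        if any(f < 0 for f in fracs):
            raise InvalidConfigError("planted fractions must be non-negative")
        if sum(self.n_planted().values()) > self.n_genes:
            raise InvalidConfigError("planted classes exceed n_genes; no room for null genes")
        if self.dispersion_median <= 0:
            raise InvalidConfigError("dispersion_median must be > 0")
        if self.library_size_factors is not None:
            lsf = np.asarray(self.library_size_factors, dtype=float)
            if lsf.shape != (self.n_samples,):
                raise InvalidConfigError(
                    f"library_size_factors must have length {self.n_samples}"
                )
            if not np.all(lsf > 0):
                raise InvalidConfigError("library size factors must be > 0")
        if self.n_stage_modules > self.n_modules:
            raise InvalidConfigError("n_stage_modules cannot exceed n_modules")


class SyntheticDataset(NamedTuple):
    counts: pd.DataFrame        # genes x samples, integer
    sample_sheet: pd.DataFrame  # sample_id, condition, week, litter, batch, age
    truth: pd.DataFrame         # per-gene planted class and effects


def _make_sample_sheet(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for condition in ("tumor", "control"):
        for week in config.weeks:
            for rep in range(1, config.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{condition}_w{week}_r{rep}",
                        "condition": condition,
                        "week": week,
                        "litter": f"L{rng.integers(1, config.n_litters + 1)}",
                        "batch": f"B{rng.integers(1, config.n_batches + 1)}",
                        "age": week,
                    }
                )
    return pd.DataFrame(rows)


def _planted_effects(config: SimulationConfig, rng: np.random.Generator):
    """Assign gene classes and per-stage log2 fold-change vectors."""
    n = config.n_genes
    counts = config.n_planted()
    classes = np.array(["null"] * n, dtype=object)
    lfc = np.zeros((n, 4))
    pattern = np.array([""] * n, dtype=object)
    module_id = np.zeros(n, dtype=int)
    loading = np.zeros(n)

    pos = 0
    # constant DEGs: same log2FC at every stage, alternating sign
    for i in range(counts["constant_deg"]):
        classes[pos] = "constant_deg"
        sign = 1.0 if i % 2 == 0 else -1.0
        lfc[pos, :] = sign * config.constant_deg_lfc
        pos += 1
    # progressive DEGs: |log2FC| strictly increasing across stages
    steps = np.array([0.25, 0.5, 0.75, 1.0]) * config.progressive_deg_lfc_max
    for i in range(counts["progressive_deg"]):
        classes[pos] = "progressive_deg"
        sign = 1.0 if i % 2 == 0 else -1.0
        lfc[pos, :] = sign * steps
        pos += 1
    # transition genes: a jump at the malignant (second) transition so the
    # planted LRC sign matches the planted pattern entry
    for i in range(counts["transition"]):
        classes[pos] = "transition"
        if i % 2 == 0:
            lfc[pos, :] = (0.0, 0.0, config.transition_lfc, config.transition_lfc)
            pattern[pos] = "0,+,0"
        else:
            lfc[pos, :] = (0.0, 0.0, -config.transition_lfc, -config.transition_lfc)
            pattern[pos] = "0,-,0"
        pos += 1
    # module members: no planted mean shift; expression driven by latent factor
    for m in range(1, config.n_modules + 1):
        for _ in range(config.module_size):
            classes[pos] = "module"
            module_id[pos] = m
            loading[pos] = config.module_loading_scale * rng.uniform(0.5, 1.0)
            pos += 1
    return classes, lfc, pattern, module_id, loading


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw a (counts, sample sheet, truth) triple under ``config``.

    Counts are NB with mean = size_factor x baseline x 2^(stage effect for
    tumor samples) x 2^(covariate effects) x 2^(loading x latent factor) and
    per-gene dispersion phi_g; identical config + seed give identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    sheet = _make_sample_sheet(config, rng)
    n_genes, n_samples = config.n_genes, config.n_samples
    gene_ids = [f"g{i:05d}" for i in range(1, n_genes + 1)]

    baseline = rng.lognormal(config.baseline_log_mean_loc, config.baseline_log_mean_scale, n_genes)
    phi = rng.lognormal(math.log(config.dispersion_median), config.dispersion_log_sd, n_genes)
    if config.library_size_factors is not None:
        size_factors = np.asarray(config.library_size_factors, dtype=float)
    else:
        size_factors = rng.lognormal(0.0, config.library_size_sigma, n_samples)

    classes, lfc, pattern, module_id, loading = _planted_effects(config, rng)

    # per-sample covariate shifts (log2 units)
    litter_eff = {f"L{k}": rng.normal(0.0, config.litter_effect_sd) for k in range(1, config.n_litters + 1)}
    batch_eff = {f"B{k}": rng.normal(0.0, config.batch_effect_sd) for k in range(1, config.n_batches + 1)}
    cov_shift = np.array(
        [litter_eff[l] + batch_eff[b] for l, b in zip(sheet["litter"], sheet["batch"])]
    )

    # latent module factors: stage-associated modules follow ordinal stage
    # (controls 0, tumor weeks 1..4) plus standard-normal noise; others pure noise
    week_rank = {w: i + 1 for i, w in enumerate(config.weeks)}
    stage_ord = np.array(
        [week_rank[w] if c == "tumor" else 0 for c, w in zip(sheet["condition"], sheet["week"])],
        dtype=float,
    )
    factors = np.zeros((config.n_modules, n_samples))
    for m in range(config.n_modules):
        noise = rng.normal(0.0, config.module_factor_noise_sd, n_samples)
        if m < config.n_stage_modules:
            f = stage_ord + noise
        else:
            f = noise
        factors[m] = f - f.mean()

    # per-gene per-sample stage effect (tumor samples only)
    is_tumor = (sheet["condition"] == "tumor").to_numpy()
    week_idx = np.array([list(config.weeks).index(w) for w in sheet["week"]])
    stage_effect = np.where(is_tumor[None, :], lfc[:, week_idx], 0.0)

    module_term = np.zeros((n_genes, n_samples))
    members = module_id > 0
    if members.any():
        module_term[members] = loading[members, None] * factors[module_id[members] - 1]
    log2_mu = (
        np.log2(baseline)[:, None] + stage_effect + cov_shift[None, :] + module_term
    )
    mu = size_factors[None, :] * np.exp2(log2_mu)

    r = 1.0 / phi
    p = r[:, None] / (r[:, None] + mu)
    counts = rng.negative_binomial(r[:, None], p)

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sheet["sample_id"].to_list())
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "class": classes,
            "lfc_w6": lfc[:, 0],
            "lfc_w8": lfc[:, 1],
            "lfc_w10": lfc[:, 2],
            "lfc_w12": lfc[:, 3],
            "pattern": pattern,
            "module_id": module_id,
            "loading": loading,
        }
    ).set_index("gene_id")
    return SyntheticDataset(counts_df, sheet, truth)


DEFAULT_TREND_SHAPES = {
    "early_peak": (1.0, 5.0, 1.0, 1.0),
    "mid_peak": (1.0, 1.0, 5.0, 1.0),
    "late_peak": (1.0, 1.0, 1.0, 5.0),
}


def simulate_trend_blobs(
    n_per_blob: int = 40,
    seed: int = 0,
    shapes: dict[str, tuple[float, float, float, float]] | None = None,
    n_replicates: int = 3,
    noise: float = 0.03,
):
    """Tumor-only normalized expression with genes in planted trend blobs.

    Each blob follows a week-6-relative expression shape over weeks
    6/8/10/12; the default shapes are stage-specific peaks whose ratio-space
    centers are pairwise equidistant.  Returns (NormalizedMatrix, sample
    sheet, true blob labels).
    """
    from .preprocess import NormalizedMatrix, add_stage_labels

    shapes = shapes or DEFAULT_TREND_SHAPES
    rng = np.random.default_rng(seed)
    weeks = STAGE_WEEKS
    sheet = pd.DataFrame(
        [
            {
                "sample_id": f"tumor_w{w}_r{r}",
                "condition": "tumor",
                "week": w,
                "litter": "L1",
                "batch": "B1",
                "age": w,
            }
            for w in weeks
            for r in range(1, n_replicates + 1)
        ]
    )
    rows, genes, labels = [], [], []
    for b, (name, shape) in enumerate(shapes.items()):
        for i in range(n_per_blob):
            base = rng.uniform(50, 150)
            vals = []
            for w_idx in range(len(weeks)):
                level = base * shape[w_idx]
                vals.extend(level * rng.uniform(1 - noise, 1 + noise, n_replicates))
            rows.append(vals)
            genes.append(f"{name}_{i}")
            labels.append(b)
    values = pd.DataFrame(np.array(rows), index=pd.Index(genes, name="gene_id"), columns=sheet["sample_id"])
    return NormalizedMatrix(values), add_stage_labels(sheet), pd.Series(labels, index=genes, name="blob")


def write_fixture(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write counts TSV, sample sheet CSV and truth TSV; round-trips losslessly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "samples": out / "samples.csv",
        "truth": out / "truth.tsv",
    }
    dataset.counts.to_csv(paths["counts"], sep="\t")
    dataset.sample_sheet.to_csv(paths["samples"], index=False)
    dataset.truth.to_csv(paths["truth"], sep="\t")
    return paths
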