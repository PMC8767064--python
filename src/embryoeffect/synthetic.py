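"""Synthetic seed-compartment omics with planted, recoverable effects.

The generator emulates the two-genotype (WT vs notched-belly mutant NB),
three-compartment (embryo E, upper endosperm EnU, bottom endosperm EnB),
three-stage (10/20/30 days after fertilization) factorial design with six
metabolome and three transcriptome replicates per cell.

Generative model for a metabolite ``f`` in genotype ``g``, tissue ``t``,
stage ``s``::

    intensity = b_f * exp(A * m(module_f, s))
                    * pi(f, s)  ** [t == EnB]
                    * eps(f, s) ** [g == NB and t == EnB]
                    * exp(sigma * z),   z ~ N(0, 1)

``pi`` is the *position* multiplier (applied to the bottom endosperm of
both genotypes), ``eps`` the *embryo* multiplier (applied only to the
bottom endosperm of the mutant, where the notched line traps the embryo's
influence).  Both are 1 for unaffected features.  Features absent from a
compartment are simply not detected there.  Everything is deterministic
given (config, seed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    COMPOUND_CLASSES,
    CatalogEntry,
    DEFAULT_STAGES,
    FeatureMatrix,
    SampleRecord,
)
from .io import write_results

logger = logging.getLogger(__name__)

#: Per-tissue class counts of the default 634-metabolite catalog.
DEFAULT_CLASS_COUNTS_EMBRYO: dict[str, int] = {
    "amino acids": 175,
    "carbohydrates": 73,
    "lipids": 175,
    "CPGEC": 38,
    "nucleotides": 64,
    "peptides": 16,
    "secondary metabolites": 43,
    "phytohormones": 6,
    "xenobiotics": 3,
}
DEFAULT_CLASS_COUNTS_ENDOSPERM: dict[str, int] = {
    "amino acids": 160,
    "carbohydrates": 65,
    "lipids": 160,
    "CPGEC": 33,
    "nucleotides": 49,
    "peptides": 17,
    "secondary metabolites": 34,
    "phytohormones": 5,
    "xenobiotics": 2,
}

# Six module archetypes as Z-score profiles over the three stages
# (sample sd 1, mean 0).  DP1-DP3 peak at a single stage; DP4-DP6 are
# high at two stages ("broad" under the 0.5-Z dominance margin).
_S3 = math.sqrt(3.0)
MODULE_ARCHETYPES: dict[str, tuple[float, float, float]] = {
    "DP1": (2 / _S3, -1 / _S3, -1 / _S3),
    "DP2": (-1 / _S3, 2 / _S3, -1 / _S3),
    "DP3": (-1 / _S3, -1 / _S3, 2 / _S3),
    "DP4": (1 / _S3, 1 / _S3, -2 / _S3),
    "DP5": (1 / _S3, -2 / _S3, 1 / _S3),
    "DP6": (-2 / _S3, 1 / _S3, 1 / _S3),
}


def scale_class_counts(total: int, reference: dict[str, int]) -> dict[str, int]:
    """Scale a class-count profile to a new total (largest remainder)."""
    if total == 0:
        return {c: 0 for c in reference}
    ref_total = sum(reference.values())
    quotas = {c: total * n / ref_total for c, n in reference.items()}
    counts = {c: int(math.floor(q)) for c, q in quotas.items()}
    short = total - sum(counts.values())
    order = sorted(
        reference,
        key=lambda c: (-(quotas[c] - counts[c]), COMPOUND_CLASSES.index(c)),
    )
    for c in order[:short]:
        counts[c] += 1
    return counts


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study, with the study design as defaults."""

    n_metabolites: int = 634
    n_shared: int = 484
    n_embryo_only: int = 109
    n_endosperm_only: int = 41
    class_counts_embryo: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS_EMBRYO)
    )
    class_counts_endosperm: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS_ENDOSPERM)
    )
    n_replicates_metabolome: int = 6
    n_replicates_transcriptome: int = 3
    stages: tuple[int, ...] = DEFAULT_STAGES
    #: standard deviation of multiplicative noise on the natural-log scale
    noise_sigma: float = 0.25
    position_effect_fraction: float = 0.2
    position_multiplier_range: tuple[float, float] = (1.5, 3.0)
    #: per-stage attenuation of log-position effects (linear decline)
    position_stage_weights: tuple[float, float, float] = (1.0, 0.65, 0.3)
    embryo_effect_fraction: float = 0.2
    embryo_multiplier_range: tuple[float, float] = (1.5, 3.0)
    #: per-stage attenuation of log-embryo effects ("V-type": strongest at
    #: 10 DAF, nearly gone at 20, partly recovered at 30)
    embryo_stage_weights: tuple[float, float, float] = (1.0, 0.2, 0.8)
    module_count: int = 6
    #: amplitude (natural-log units) of the module stage profiles
    module_amplitude: float = 0.8
    n_genes: int = 2000
    gene_unexpressed_fraction: float = 0.1
    gene_deg_fraction: float = 0.1
    gene_deg_log2_range: tuple[float, float] = (1.0, 2.0)
    seed: int = 0

    def validate(self) -> None:
        if (
            self.n_shared + self.n_embryo_only + self.n_endosperm_only
            != self.n_metabolites
        ):
            raise ValueError(
                "n_shared + n_embryo_only + n_endosperm_only = "
                f"{self.n_shared + self.n_embryo_only + self.n_endosperm_only}"
                f" != n_metabolites = {self.n_metabolites}"
            )
        e_total = sum(self.class_counts_embryo.values())
        if e_total != self.n_shared + self.n_embryo_only:
            raise ValueError(
                f"embryo class counts sum to {e_total}, expected "
                f"{self.n_shared + self.n_embryo_only}"
            )
        n_total = sum(self.class_counts_endosperm.values())
        if n_total != self.n_shared + self.n_endosperm_only:
            raise ValueError(
                f"endosperm class counts sum to {n_total}, expected "
                f"{self.n_shared + self.n_endosperm_only}"
            )
        for counts in (self.class_counts_embryo, self.class_counts_endosperm):
            unknown = set(counts) - set(COMPOUND_CLASSES)
            if unknown:
                raise ValueError(f"unknown compound class(es): {sorted(unknown)}")
        for frac in (self.position_effect_fraction, self.embryo_effect_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"effect fraction {frac} outside [0, 1]")
        for lo, hi in (
            self.position_multiplier_range,
            self.embryo_multiplier_range,
        ):
            if not (1.0 < lo <= hi):
                raise ValueError("multiplier range must satisfy 1 < lo <= hi")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not 1 <= self.module_count <= len(MODULE_ARCHETYPES):
            raise ValueError(
                f"module_count must be in [1, {len(MODULE_ARCHETYPES)}]"
            )

    @classmethod
    def with_counts(
        cls,
        n_shared: int,
        n_embryo_only: int = 0,
        n_endosperm_only: int = 0,
        **kwargs,
    ) -> "GeneratorConfig":
        """Build a consistent config for an arbitrary catalog size, keeping
        the default class-composition proportions.

        The shared and per-tissue exclusive compositions are scaled
        separately so the per-class counts always admit the requested
        shared/exclusive partition.
        """
        default = cls()
        default_shared = _shared_class_counts(default)
        default_embryo_only = {
            c: default.class_counts_embryo.get(c, 0) - default_shared.get(c, 0)
            for c in COMPOUND_CLASSES
        }
        default_endosperm_only = {
            c: default.class_counts_endosperm.get(c, 0)
            - default_shared.get(c, 0)
            for c in COMPOUND_CLASSES
        }
        shared = scale_class_counts(n_shared, default_shared)
        emb_x = scale_class_counts(n_embryo_only, default_embryo_only)
        endo_x = scale_class_counts(n_endosperm_only, default_endosperm_only)
        cfg = cls(
            n_metabolites=n_shared + n_embryo_only + n_endosperm_only,
            n_shared=n_shared,
            n_embryo_only=n_embryo_only,
            n_endosperm_only=n_endosperm_only,
            class_counts_embryo={
                c: shared[c] + emb_x[c] for c in COMPOUND_CLASSES
            },
            class_counts_endosperm={
                c: shared[c] + endo_x[c] for c in COMPOUND_CLASSES
            },
            **kwargs,
        )
        cfg.validate()
        return cfg

    def null(self) -> "GeneratorConfig":
        """A copy with all planted effects switched off."""
        return replace(
            self, position_effect_fraction=0.0, embryo_effect_fraction=0.0
        )


def _shared_class_counts(config: GeneratorConfig) -> dict[str, int]:
    """Split class counts into shared/exclusive deterministically.

    Per class the shared count starts at min(embryo, endosperm) and the
    surplus over ``n_shared`` is removed by largest-remainder proportional
    reduction; exclusive counts follow by subtraction and automatically
    sum to the configured totals.
    """
    e, n = config.class_counts_embryo, config.class_counts_endosperm
    mins = {c: min(e.get(c, 0), n.get(c, 0)) for c in COMPOUND_CLASSES}
    total_min = sum(mins.values())
    if total_min < config.n_shared:
        raise ValueError(
            f"class counts admit at most {total_min} shared metabolites, "
            f"but n_shared = {config.n_shared}"
        )
    excess = total_min - config.n_shared
    quotas = {c: excess * mins[c] / total_min if total_min else 0.0 for c in mins}
    red = {c: int(math.floor(q)) for c, q in quotas.items()}
    short = excess - sum(red.values())
    order = sorted(
        mins, key=lambda c: (-(quotas[c] - red[c]), COMPOUND_CLASSES.index(c))
    )
    for c in order[:short]:
        red[c] += 1
    return {c: mins[c] - red[c] for c in mins}


def generate_catalog(config: GeneratorConfig) -> list[CatalogEntry]:
    """Generate the metabolite catalog: ids, classes, compartment presence."""
    config.validate()
    shared = _shared_class_counts(config)
    slots: list[tuple[str, frozenset[str]]] = []
    both = frozenset({"embryo", "endosperm"})
    emb = frozenset({"embryo"})
    endo = frozenset({"endosperm"})
    for c in COMPOUND_CLASSES:
        s = shared.get(c, 0)
        e_x = config.class_counts_embryo.get(c, 0) - s
        n_x = config.class_counts_endosperm.get(c, 0) - s
        slots.extend([(c, both)] * s)
        slots.extend([(c, emb)] * e_x)
        slots.extend([(c, endo)] * n_x)
    assert len(slots) == config.n_metabolites
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(slots))
    width = max(4, len(str(config.n_metabolites)))
    catalog = [
        CatalogEntry(f"M{i + 1:0{width}d}", *slots[j])
        for i, j in enumerate(order)
    ]
    return catalog


def _metabolome_records(config: GeneratorConfig) -> list[SampleRecord]:
    recs = []
    for g in ("WT", "NB"):
        for t in ("E", "EnU", "EnB"):
            for s in config.stages:
                for r in range(1, config.n_replicates_metabolome + 1):
                    recs.append(SampleRecord(f"{g}_{t}_{s}_r{r}", g, t, s, r))
    return recs


def _transcriptome_records(config: GeneratorConfig) -> list[SampleRecord]:
    recs = []
    for g in ("WT", "NB"):
        for t in ("E", "EnU", "EnB"):
            for s in config.stages:
                for r in range(1, config.n_replicates_transcriptome + 1):
                    recs.append(SampleRecord(f"{g}_{t}_{s}_r{r}", g, t, s, r))
    return recs


def _draw_multipliers(
    rng: np.random.Generator,
    n_eligible: int,
    fraction: float,
    mult_range: tuple[float, float],
) -> np.ndarray:
    """Log-multipliers for a planted effect: a ``fraction`` of eligible
    features is affected, half up with multiplier log-uniform in
    ``mult_range`` and half down with the reciprocal; the rest get 0."""
    log_mult = np.zeros(n_eligible)
    n_affected = int(round(fraction * n_eligible))
    idx = rng.choice(n_eligible, size=n_affected, replace=False)
    lo, hi = np.log(mult_range[0]), np.log(mult_range[1])
    mags = rng.uniform(lo, hi, size=n_affected)
    signs = np.ones(n_affected)
    signs[n_affected // 2:] = -1.0
    rng.shuffle(signs)
    log_mult[idx] = signs * mags
    return log_mult


def simulate_metabolome(
    config: GeneratorConfig,
    catalog: Sequence[CatalogEntry] | None = None,
    seed: int | None = None,
) -> tuple[FeatureMatrix, pd.DataFrame, list[SampleRecord]]:
    """Simulate the 108-sample metabolome and its ground truth.

    Returns (matrix with sample records attached, truth table, records).
    The truth table has one row per feature x stage with the true position
    multiplier ``pi``, embryo multiplier ``epsilon``, module label and
    compartment presence.
    """
    config.validate()
    if catalog is None:
        catalog = generate_catalog(config)
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    records = _metabolome_records(config)
    n_feat = len(catalog)
    feature_ids = [c.feature_id for c in catalog]
    stages = list(config.stages)

    modules = rng.integers(0, config.module_count, size=n_feat)
    module_names = list(MODULE_ARCHETYPES)[: config.module_count]
    arch = np.array([MODULE_ARCHETYPES[m] for m in module_names])  # k x 3
    log_base = np.log(10.0) * rng.uniform(3.0, 5.0, size=n_feat)

    in_endosperm = np.array(
        ["endosperm" in c.tissue_presence for c in catalog]
    )
    in_embryo = np.array(["embryo" in c.tissue_presence for c in catalog])

    # planted effects live on endosperm-present features only
    endo_idx = np.flatnonzero(in_endosperm)
    log_pi = np.zeros(n_feat)
    log_eps = np.zeros(n_feat)
    log_pi[endo_idx] = _draw_multipliers(
        rng,
        len(endo_idx),
        config.position_effect_fraction,
        config.position_multiplier_range,
    )
    log_eps[endo_idx] = _draw_multipliers(
        rng,
        len(endo_idx),
        config.embryo_effect_fraction,
        config.embryo_multiplier_range,
    )

    w_pos = dict(zip(stages, config.position_stage_weights))
    w_emb = dict(zip(stages, config.embryo_stage_weights))

    n_samp = len(records)
    log_mu = np.empty((n_feat, n_samp))
    for j, rec in enumerate(records):
        s_idx = stages.index(rec.stage)
        col = log_base + config.module_amplitude * arch[modules, s_idx]
        if rec.tissue == "EnB":
            col = col + w_pos[rec.stage] * log_pi
            if rec.genotype == "NB":
                col = col + w_emb[rec.stage] * log_eps
        log_mu[:, j] = col
    noise = rng.standard_normal((n_feat, n_samp)) * config.noise_sigma
    values = np.exp(log_mu + noise)

    # detection mask from compartment presence
    for j, rec in enumerate(records):
        present = in_embryo if rec.tissue == "E" else in_endosperm
        values[~present, j] = np.nan

    frame = pd.DataFrame(
        values, index=feature_ids, columns=[r.sample_id for r in records]
    )
    matrix = FeatureMatrix(frame, "metabolome", list(records))

    rows = []
    for i, entry in enumerate(catalog):
        presence = "+".join(sorted(entry.tissue_presence))
        for s in stages:
            pi_fs = math.exp(w_pos[s] * log_pi[i]) if in_endosperm[i] else 1.0
            eps_fs = math.exp(w_emb[s] * log_eps[i]) if in_endosperm[i] else 1.0
            rows.append(
                {
                    "feature_id": entry.feature_id,
                    "stage": s,
                    "pi": pi_fs,
                    "epsilon": eps_fs,
                    "module": module_names[modules[i]],
                    "tissue_presence": presence,
                }
            )
    truth = pd.DataFrame(rows)
    return matrix, truth, records


def simulate_transcriptome(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[FeatureMatrix, pd.DataFrame, list[SampleRecord]]:
    """Simulate the 54-sample FPKM table with planted DEGs.

    A fraction of genes sits below the expressed threshold everywhere.
    The planted differential contrast is NB_EnB vs WT_EnB at 10 DAF:
    "transporter" genes go up and "synthesis" genes go down, each with
    |log2 effect| >= 1.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    # offset so the transcriptome stream differs from the metabolome's
    rng = np.random.default_rng((seed + 104729) % (2**31))
    records = _transcriptome_records(config)
    n_genes = config.n_genes
    stages = list(config.stages)
    width = max(4, len(str(n_genes)))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(n_genes)]

    n_unexpr = int(round(config.gene_unexpressed_fraction * n_genes))
    unexpressed = np.zeros(n_genes, dtype=bool)
    unexpressed[rng.choice(n_genes, size=n_unexpr, replace=False)] = True

    module_names = list(MODULE_ARCHETYPES)[: config.module_count]
    arch = np.array([MODULE_ARCHETYPES[m] for m in module_names])
    modules = rng.integers(0, config.module_count, size=n_genes)

    log_base = np.log(10.0) * rng.uniform(0.5, 2.5, size=n_genes)
    # low enough that stage profile + noise cannot push FPKM past 1
    log_base[unexpressed] = np.log(0.05)

    expressed_idx = np.flatnonzero(~unexpressed)
    n_deg = int(round(config.gene_deg_fraction * len(expressed_idx)))
    deg_idx = rng.choice(expressed_idx, size=n_deg, replace=False)
    lo, hi = config.gene_deg_log2_range
    log2_eff = rng.uniform(lo, hi, size=n_deg)
    roles = np.array(["none"] * n_genes, dtype=object)
    half = n_deg // 2
    roles[deg_idx[:half]] = "transporter"  # planted up in NB_EnB at 10 DAF
    roles[deg_idx[half:]] = "synthesis"  # planted down
    log2_effect = np.zeros(n_genes)
    log2_effect[deg_idx[:half]] = log2_eff[:half]
    log2_effect[deg_idx[half:]] = -log2_eff[half:]

    n_samp = len(records)
    log_mu = np.empty((n_genes, n_samp))
    for j, rec in enumerate(records):
        s_idx = stages.index(rec.stage)
        col = log_base + config.module_amplitude * arch[modules, s_idx]
        if rec.genotype == "NB" and rec.tissue == "EnB" and rec.stage == stages[0]:
            col = col + np.log(2.0) * log2_effect
        log_mu[:, j] = col
    noise = rng.standard_normal((n_genes, n_samp)) * config.noise_sigma
    values = np.exp(log_mu + noise)

    frame = pd.DataFrame(
        values, index=gene_ids, columns=[r.sample_id for r in records]
    )
    matrix = FeatureMatrix(frame, "transcriptome", list(records))

    truth = pd.DataFrame(
        {
            "feature_id": gene_ids,
            "role": roles,
            "log2_effect_stage10": log2_effect,
            "planted_unexpressed": unexpressed,
            "module": [module_names[m] for m in modules],
        }
    )
    return matrix, truth, records


def emit_truth(truth: pd.DataFrame, path) -> None:
    """Write a ground-truth table with deterministic ordering."""
    write_results(truth, path)
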