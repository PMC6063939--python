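"""Synthetic genotype/phenotype cohorts for benchmarking phenotyping channels.

The generator emulates a biobank-style case/control study observed through
several imperfect EHR labeling channels:

* biallelic autosomal genotypes in Hardy-Weinberg equilibrium, with an
  optional two-or-more subpopulation structure (Balding-Nichols model);
* a liability-threshold polygenic disease: liability = genetic score +
  Gaussian residual, with the genetic share of variance fixed at
  ``h2_liability`` and disease status assigned above the standard-normal
  quantile implied by ``prevalence``;
* binary observation channels, each a (sensitivity, specificity)
  misclassification of the true status — defaults mimic billing codes
  (high sensitivity / low specificity), a clinician problem list (low
  sensitivity / high specificity) and a curated phenotyping algorithm
  (balanced, high accuracy);
* per-patient billing occurrence counts, where truly affected billed
  patients accumulate more repeat bills than false-positive ones.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, GenotypeMatrix
from .plink import read_phenotypes, read_plink, write_phenotypes, write_plink

__all__ = [
    "ChannelSpec",
    "SimConfig",
    "TrueCohort",
    "default_channels",
    "simulate_genotypes",
    "inject_missing",
    "simulate_disease",
    "apply_label_channel",
    "simulate_billing_counts",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]


@dataclass(frozen=True)
class ChannelSpec:
    """An imperfect binary labeler of disease status.

    ``sensitivity`` is P(label=1 | case), ``specificity`` is
    P(label=0 | control).
    """

    name: str
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("channel name must be non-empty")
        for f in ("sensitivity", "specificity"):
            v = getattr(self, f)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValueError(f"ChannelSpec.{f} must be in [0, 1], got {v}")


def default_channels() -> tuple[ChannelSpec, ...]:
    """The three default EHR labeling channels.

    Sensitivity/specificity values are qualitative stand-ins for the three
    extraction methods: billing codes find nearly every case but admit many
    false positives; the problem list is curated (few false positives) but
    misses many cases; the phenotyping algorithm is accurate on both axes.
    """
    return (
        ChannelSpec("billing", sensitivity=0.95, specificity=0.90),
        ChannelSpec("problem_list", sensitivity=0.60, specificity=0.995),
        ChannelSpec("algorithm", sensitivity=0.80, specificity=0.995),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study-design knobs for one synthetic cohort.

    Defaults describe the reference scenario used throughout the test
    battery: 4000 samples x 5000 independent variants, 50 causal variants,
    liability heritability 0.5, prevalence 5%, one ancestry.
    """

    n_samples: int = 4000
    n_variants: int = 5000
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_causal: int = 50
    h2_liability: float = 0.5
    prevalence: float = 0.05
    n_subpops: int = 1
    fst: float = 0.0
    channels: tuple[ChannelSpec, ...] = field(default_factory=default_channels)
    billing_count_params: tuple[float, float] = (2.0, 0.3)
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        def _bad(name, msg):
            raise ValueError(f"SimConfig.{name}: {msg}")

        for name in ("n_samples", "n_variants", "n_causal", "n_subpops"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                _bad(name, f"must be a nonnegative integer, got {v!r}")
        if self.n_samples < 1 or self.n_variants < 1:
            _bad("n_samples/n_variants", "must be positive")
        if self.n_subpops < 1:
            _bad("n_subpops", "must be >= 1")
        if self.n_causal > self.n_variants:
            _bad("n_causal", "cannot exceed n_variants")
        for name, lo, hi in (
            ("maf_low", 0.0, 0.5),
            ("maf_high", 0.0, 0.5),
            ("h2_liability", 0.0, 1.0),
            ("missing_rate", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or not lo <= v <= hi:
                _bad(name, f"must be in [{lo}, {hi}], got {v!r}")
        if self.maf_low > self.maf_high:
            _bad("maf_low", "must be <= maf_high")
        if self.maf_low <= 0.0:
            _bad("maf_low", "must be > 0")
        if not np.isfinite(self.prevalence) or not 0.0 < self.prevalence < 1.0:
            _bad("prevalence", f"must be in (0, 1), got {self.prevalence!r}")
        if not np.isfinite(self.fst) or not 0.0 <= self.fst < 1.0:
            _bad("fst", f"must be in [0, 1), got {self.fst!r}")
        if self.n_subpops > 1 and self.fst <= 0.0:
            _bad("fst", "must be > 0 when n_subpops > 1")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            _bad("channels", f"duplicate channel names in {names}")
        case_extra, fp_extra = self.billing_count_params
        if case_extra < 0 or fp_extra < 0:
            _bad("billing_count_params", "means must be nonnegative")


@dataclass
class TrueCohort:
    """A fully observed synthetic cohort, including simulation ground truth."""

    genotypes: GenotypeMatrix
    liability: np.ndarray
    true_status: np.ndarray
    labels: pd.DataFrame            # one {0,1} column per channel, sample order
    billing_counts: np.ndarray
    subpop: np.ndarray              # subpopulation index per sample
    causal_idx: np.ndarray          # variant indices carrying effects
    effects: np.ndarray             # per-causal-variant standardized effect

    @property
    def channel_names(self) -> list[str]:
        return list(self.labels.columns)

    def phenotype_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"sample_id": self.genotypes.sample_ids})
        out["true_status"] = self.true_status.astype(int)
        for name in self.labels.columns:
            out[name] = self.labels[name].to_numpy().astype(int)
        out["billing_count"] = self.billing_counts.astype(int)
        return out


# --------------------------------------------------------------------------
# genotypes


def _subpop_assignment(n_samples: int, n_subpops: int) -> np.ndarray:
    """Deterministic contiguous-block assignment of samples to subpopulations."""
    return (np.arange(n_samples) * n_subpops) // n_samples


def simulate_genotypes(config: SimConfig, seed: int | None = None) -> GenotypeMatrix:
    """Draw HWE genotypes with per-variant frequencies ~ U(maf_low, maf_high).

    With ``n_subpops > 1`` the uniform draw is the ancestral frequency and
    each subpopulation's frequency is drawn from the Balding-Nichols beta
    distribution with parameter ``fst``; samples are assigned to
    subpopulations in contiguous equal blocks.  Genotypes are complete
    (no missing calls) — see :func:`inject_missing`.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, m = config.n_samples, config.n_variants
    p_anc = rng.uniform(config.maf_low, config.maf_high, size=m)
    subpop = _subpop_assignment(n, config.n_subpops)
    if config.n_subpops > 1:
        F = config.fst
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        p_sub = rng.beta(a[None, :], b[None, :], size=(config.n_subpops, m))
        p_sub = np.clip(p_sub, 1e-6, 1.0 - 1e-6)
        dosages = rng.binomial(2, p_sub[subpop, :]).astype(np.int8)
    else:
        dosages = rng.binomial(2, p_anc[None, :], size=(n, m)).astype(np.int8)

    width_v = len(str(m))
    width_s = len(str(n))
    return GenotypeMatrix(
        dosages=dosages,
        variant_ids=np.array([f"snp{i + 1:0{width_v}d}" for i in range(m)]),
        chrom=np.ones(m, dtype=np.int64),
        pos=np.arange(1, m + 1, dtype=np.int64),
        allele1=np.repeat("A", m),
        allele2=np.repeat("B", m),
        sample_ids=np.array([f"id{i + 1:0{width_s}d}" for i in range(n)]),
    )


def inject_missing(gm: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Set a Bernoulli(rate) subset of calls to missing."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"missing rate must be in [0, 1], got {rate}")
    if rate == 0.0:
        return gm
    rng = np.random.default_rng(seed)
    mask = rng.random(gm.dosages.shape) < rate
    dosages = np.where(mask, np.int8(MISSING), gm.dosages)
    return GenotypeMatrix(
        dosages=dosages,
        variant_ids=gm.variant_ids,
        chrom=gm.chrom,
        pos=gm.pos,
        allele1=gm.allele1,
        allele2=gm.allele2,
        sample_ids=gm.sample_ids,
    )


# --------------------------------------------------------------------------
# disease model


def simulate_disease(
    genotypes: GenotypeMatrix, config: SimConfig, seed: int | None = None
) -> TrueCohort:
    """Liability-threshold disease on top of *genotypes*.

    ``n_causal`` variants are sampled without replacement; their standardized
    dosages receive i.i.d. normal effects, and the resulting genetic score is
    empirically rescaled to variance ``h2_liability``.  The residual is
    N(0, 1 - h2), and status is 1 when liability exceeds the standard-normal
    (1 - prevalence) quantile.  Labels/billing counts are left empty here.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, m = genotypes.n_samples, genotypes.n_variants
    if config.n_causal > m:
        raise ValueError("n_causal exceeds the number of variants")
    h2 = config.h2_liability

    causal_idx = np.sort(rng.choice(m, size=config.n_causal, replace=False))
    effects = rng.standard_normal(config.n_causal)

    if h2 > 0 and config.n_causal > 0:
        Z = genotypes.take_variants(causal_idx).standardized()
        raw = Z @ effects
        sd = raw.std()
        if sd == 0.0:
            raise ValueError(
                "causal genetic score has zero variance "
                "(monomorphic causal set) but h2_liability > 0"
            )
        genetic = raw * (np.sqrt(h2) / sd)
    else:
        genetic = np.zeros(n)

    residual = rng.standard_normal(n) * np.sqrt(1.0 - h2)
    liability = genetic + residual
    threshold = stats.norm.isf(config.prevalence)
    true_status = (liability > threshold).astype(np.int8)

    return TrueCohort(
        genotypes=genotypes,
        liability=liability,
        true_status=true_status,
        labels=pd.DataFrame(index=range(n)),
        billing_counts=np.zeros(n, dtype=np.int64),
        subpop=_subpop_assignment(n, config.n_subpops),
        causal_idx=causal_idx,
        effects=effects,
    )


# --------------------------------------------------------------------------
# observation channels


def apply_label_channel(
    true_status: np.ndarray, spec: ChannelSpec, seed: int
) -> np.ndarray:
    """Misclassify *true_status* through one (sensitivity, specificity) channel."""
    true_status = np.asarray(true_status)
    rng = np.random.default_rng(seed)
    u = rng.random(true_status.shape)
    labels = np.where(
        true_status == 1, u < spec.sensitivity, u < (1.0 - spec.specificity)
    )
    return labels.astype(np.int8)


def simulate_billing_counts(
    true_status: np.ndarray,
    billing_labels: np.ndarray,
    params: tuple[float, float],
    seed: int,
) -> np.ndarray:
    """Billing occurrence counts: 1 + Poisson extras for billed patients.

    Billed true cases draw extras with mean ``params[0]``, billed false
    positives with mean ``params[1]``; unbilled patients stay at 0.  With the
    default (2.0, 0.3) the positive predictive value of "billed at least t
    times" rises with t.
    """
    case_extra, fp_extra = params
    if case_extra < 0 or fp_extra < 0:
        raise ValueError("billing count means must be nonnegative")
    true_status = np.asarray(true_status).astype(bool)
    billed = np.asarray(billing_labels).astype(bool)
    rng = np.random.default_rng(seed)
    means = np.where(true_status, case_extra, fp_extra)
    counts = np.where(billed, 1 + rng.poisson(means), 0)
    return counts.astype(np.int64)


# --------------------------------------------------------------------------
# orchestration

# Sub-stream indices for SeedSequence spawning; documented so any stage can
# be re-run in isolation from the same top-level seed.
_STREAM_GENOTYPES = 0
_STREAM_DISEASE = 1
_STREAM_MISSING = 2
_STREAM_BILLING = 3
_STREAM_CHANNEL_BASE = 10  # channel i uses stream _STREAM_CHANNEL_BASE + i


def stage_seed(seed: int, stream: int) -> int:
    """Derive the integer seed of sub-stream *stream* from a global seed."""
    child = np.random.SeedSequence(seed, spawn_key=(stream,))
    return int(child.generate_state(1, dtype=np.uint32)[0])


def simulate_cohort(config: SimConfig) -> TrueCohort:
    """Full generative pass: genotypes -> disease -> channels -> billing.

    Missing calls are injected only after the disease is generated, so the
    liability reflects the true (complete) genotypes while downstream QC
    sees realistic missingness.
    """
    seed = config.seed
    gm = simulate_genotypes(config, seed=stage_seed(seed, _STREAM_GENOTYPES))
    cohort = simulate_disease(gm, config, seed=stage_seed(seed, _STREAM_DISEASE))
    cohort.genotypes = inject_missing(
        gm, config.missing_rate, seed=stage_seed(seed, _STREAM_MISSING)
    )

    labels = {}
    for i, spec in enumerate(config.channels):
        labels[spec.name] = apply_label_channel(
            cohort.true_status, spec, seed=stage_seed(seed, _STREAM_CHANNEL_BASE + i)
        )
    cohort.labels = pd.DataFrame(labels)

    if "billing" in cohort.labels.columns:
        cohort.billing_counts = simulate_billing_counts(
            cohort.true_status,
            cohort.labels["billing"].to_numpy(),
            config.billing_count_params,
            seed=stage_seed(seed, _STREAM_BILLING),
        )
    return cohort


# --------------------------------------------------------------------------
# persistence


def write_cohort(cohort: TrueCohort, out_prefix) -> None:
    """Write the PLINK triplet and the phenotype TSV for *cohort*."""
    if cohort.genotypes.n_samples == 0:
        raise ValueError("empty cohort")
    write_plink(cohort.genotypes, out_prefix)
    from pathlib import Path

    prefix = Path(out_prefix)
    write_phenotypes(cohort.phenotype_frame(), Path(str(prefix) + ".pheno.tsv"))


def read_cohort(prefix) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read back what :func:`write_cohort` wrote (genotypes + phenotype table)."""
    from pathlib import Path

    prefix = Path(prefix)
    gm = read_plink(prefix)
    pheno = read_phenotypes(Path(str(prefix) + ".pheno.tsv"))
    return gm, pheno
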