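"""Synthetic two-sample GWAS summary statistics with known truth.

The generator draws summary statistics directly from their asymptotic
sampling distributions — no individual-level genotypes — which is fast
and gives exact control of the generating truth:

* allele frequencies f_j uniform over a configurable range;
* true SNP-exposure effects gamma_j (SD units) with relative magnitudes
  uniform on [0.5, 1.5], scaled so the variance explained
  sum_j 2 gamma_j² f_j (1-f_j) equals the target R² exactly (selected
  genome-wide-significant instruments are bounded away from zero, so a
  bounded relative-magnitude draw is used rather than a half-normal);
* exposure estimates gamma_hat_j ~ N(gamma_j, sx_j²) with
  sx_j² = (1-R²) / (n_exposure * 2 f_j (1-f_j));
* true SNP-outcome effects Gamma_j = beta_causal * gamma_j + alpha_j,
  where the pleiotropic effects alpha_j are zero for valid instruments
  and drawn N(mean_alpha, sd_alpha²) (directional) or N(0, sd_alpha²)
  (balanced) for a configurable invalid fraction;
* binary-outcome estimates Gamma_hat_j ~ N(Gamma_j, sy_j²) on the
  log-OR scale with the logistic score approximation
  sy_j² = 1 / (n_outcome * K (1-K) * 2 f_j (1-f_j)), K the case fraction.

Exposure and outcome noise are drawn independently (two-sample design,
no sample overlap). Defaults mirror a 10-instrument vitamin C exposure
(R² = 0.0187, n = 52,018) against a large breast-cancer case-control
outcome (N = 247,173, 133,384 cases).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .harmonize import LDReference
from .sumstats import StudyPanel, VariantAssociation

# non-palindromic allele pairs cycled across simulated variants
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("T", "C"), ("G", "A"))


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PleiotropyConfig:
    mode: str = "none"  # none | balanced | directional
    mean_alpha: float = 0.0
    sd_alpha: float = 0.0
    invalid_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "balanced", "directional"):
            raise SimulationError(f"unknown pleiotropy mode {self.mode!r}")
        if not 0.0 <= self.invalid_fraction <= 1.0:
            raise SimulationError("invalid_fraction outside [0, 1]")


@dataclass(frozen=True)
class LDBlockConfig:
    """Optional proxy block around the first index SNP: size-1 extra
    variants with pairwise signed correlation rho, present in the
    outcome panel (and the LD reference) for proxy-substitution tests."""

    size: int = 1
    rho: float = 0.9
    drop_index_from_outcome: bool = False


@dataclass(frozen=True)
class SimConfig:
    n_snps: int = 10
    maf_range: tuple[float, float] = (0.1, 0.5)
    target_r2: float = 0.0187
    n_exposure: int = 52018
    n_outcome: int = 247173
    case_fraction: float = 133384 / 247173
    beta_causal: float = 0.0
    pleiotropy: PleiotropyConfig = field(default_factory=PleiotropyConfig)
    ld_block: LDBlockConfig = field(default_factory=LDBlockConfig)
    seed: int | tuple[int, ...] = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise SimulationError("n_snps must be >= 1")
        if not 0.0 < self.case_fraction < 1.0:
            raise SimulationError("case_fraction outside (0, 1)")
        if not 0.0 < self.target_r2 < 1.0:
            raise SimulationError("target_r2 outside (0, 1)")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi < 1.0:
            raise SimulationError(f"bad maf_range {self.maf_range}")


@dataclass
class SimTruth:
    """Generating parameters of one synthetic dataset."""

    beta_causal: float
    gamma: np.ndarray  # true SNP-exposure effects
    alpha: np.ndarray  # true direct SNP-outcome effects
    realized_r2: float
    invalid_idx: list[int]

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "beta_causal": self.beta_causal,
            "gamma": self.gamma.tolist(),
            "alpha": self.alpha.tolist(),
            "realized_r2": self.realized_r2,
            "invalid_idx": self.invalid_idx,
        }
        Path(path).write_text(json.dumps(payload, indent=2))
        return Path(path)


@dataclass
class SimResult:
    exposure: StudyPanel
    outcome: StudyPanel
    ld: LDReference
    truth: SimTruth

    def __iter__(self):
        return iter((self.exposure, self.outcome, self.ld, self.truth))


def _two_sided_p(beta: float, se: float) -> float:
    # floor avoids p = 0, which record validation rejects
    return max(float(2.0 * norm.sf(abs(beta) / se)), 5e-324)


def simulate_two_sample(config: SimConfig) -> SimResult:
    """Generate one two-sample dataset (exposure panel, outcome panel,
    LD reference, truth) under ``config``. Fully seeded."""
    cfg = config
    J = cfg.n_snps
    rng = np.random.default_rng(cfg.seed)

    f = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], J)
    g_rel = rng.uniform(0.5, 1.5, J)
    denom = float(np.sum(2.0 * g_rel**2 * f * (1 - f)))
    if denom <= 0:
        raise SimulationError("target_r2 unreachable: degenerate frequencies")
    gamma = g_rel * math.sqrt(cfg.target_r2 / denom)
    realized_r2 = float(np.sum(2.0 * gamma**2 * f * (1 - f)))

    sx = np.sqrt((1.0 - cfg.target_r2) / (cfg.n_exposure * 2.0 * f * (1 - f)))
    gamma_hat = rng.normal(gamma, sx)

    alpha = np.zeros(J)
    invalid_idx: list[int] = []
    pl = cfg.pleiotropy
    if pl.mode != "none" and pl.invalid_fraction > 0:
        n_invalid = int(round(pl.invalid_fraction * J))
        invalid_idx = sorted(rng.choice(J, size=n_invalid, replace=False).tolist())
        mean = pl.mean_alpha if pl.mode == "directional" else 0.0
        alpha[invalid_idx] = rng.normal(mean, pl.sd_alpha, n_invalid)

    K = cfg.case_fraction
    Gamma = cfg.beta_causal * gamma + alpha
    sy = np.sqrt(1.0 / (cfg.n_outcome * K * (1 - K) * 2.0 * f * (1 - f)))
    Gamma_hat = rng.normal(Gamma, sy)

    n_cases = int(round(cfg.n_outcome * K))
    n_controls = cfg.n_outcome - n_cases

    exposure = StudyPanel("sim_exposure", "continuous", sd_units="1 SD")
    outcome = StudyPanel(
        "sim_outcome", "binary", n_cases=n_cases, n_controls=n_controls
    )
    snp_ids = [f"rs{1000 + i}" for i in range(J)]
    for i, snp in enumerate(snp_ids):
        ea, oa = _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)]
        common = dict(
            chrom=str(i % 22 + 1),
            pos=100_000 * (i + 1),
            effect_allele=ea,
            other_allele=oa,
            eaf=float(f[i]),
        )
        exposure.add(
            VariantAssociation(
                snp_id=snp,
                beta=float(gamma_hat[i]),
                se=float(sx[i]),
                pvalue=_two_sided_p(gamma_hat[i], sx[i]),
                n=cfg.n_exposure,
                **common,
            )
        )
        outcome.add(
            VariantAssociation(
                snp_id=snp,
                beta=float(Gamma_hat[i]),
                se=float(sy[i]),
                pvalue=_two_sided_p(Gamma_hat[i], sy[i]),
                n=cfg.n_outcome,
                n_cases=n_cases,
                n_controls=n_controls,
                **common,
            )
        )

    ld = LDReference(sample_n=503)
    blk = cfg.ld_block
    if blk.size > 1:
        index = snp_ids[0]
        idx_rec = outcome[index]
        rho = blk.rho
        proxies = []
        for k in range(1, blk.size):
            pid = f"{index}_p{k}"
            proxies.append(pid)
            ld.add(index, pid, rho)
            # proxy's per-allele outcome effect attenuated by rho
            Gp = rho * Gamma[0]
            Gp_hat = float(rng.normal(Gp, sy[0]))
            outcome.add(
                VariantAssociation(
                    snp_id=pid,
                    chrom=idx_rec.chrom,
                    pos=idx_rec.pos + 500 * k,
                    effect_allele=idx_rec.effect_allele,
                    other_allele=idx_rec.other_allele,
                    eaf=idx_rec.eaf,
                    beta=Gp_hat,
                    se=float(sy[0]),
                    pvalue=_two_sided_p(Gp_hat, sy[0]),
                    n=cfg.n_outcome,
                    n_cases=n_cases,
                    n_controls=n_controls,
                )
            )
        for a in range(len(proxies)):
            for b in range(a + 1, len(proxies)):
                ld.add(proxies[a], proxies[b], rho * rho)
        if blk.drop_index_from_outcome:
            del outcome.records[index]

    truth = SimTruth(
        beta_causal=cfg.beta_causal,
        gamma=gamma,
        alpha=alpha,
        realized_r2=realized_r2,
        invalid_idx=invalid_idx,
    )
    return SimResult(exposure, outcome, ld, truth)


# --- vitamin C demonstration fixture -------------------------------------

#: the 11 plasma vitamin C loci: a known SLC23A1 variant plus ten further
#: genome-wide-significant loci; rs174547 (FADS1) is blacklisted for its
#: broad lipid pleiotropy.
VITAMIN_C_LOCI: tuple[tuple[str, str, str], ...] = (
    ("rs33972313", "5", "SLC23A1"),
    ("rs6693447", "1", "RER1"),
    ("rs13028225", "2", "SLC23A3"),
    ("rs10051765", "5", "RGS14"),
    ("rs7740812", "6", "GSTA5"),
    ("rs174547", "11", "FADS1"),
    ("rs117885456", "12", "SNRPF"),
    ("rs2559850", "12", "CHPT1"),
    ("rs10136000", "14", "AKT1"),
    ("rs56738967", "16", "MAF"),
    ("rs9895661", "17", "BCAS3"),
)

VITAMIN_C_BLACKLIST = frozenset({"rs174547"})

VITAMIN_C_GWAS_N = 52018
VITAMIN_C_R2 = 0.0187


def make_vitaminc_fixture() -> tuple[StudyPanel, frozenset[str]]:
    """An 11-SNP plasma vitamin C exposure panel with synthetic effect
    sizes (deterministic; positions and effects are NOT the published
    ones) scaled so the variance explained is exactly 0.0187, plus the
    rs174547 blacklist. Demonstrates the 11 -> 10 instrument selection.
    """
    panel = StudyPanel(
        "vitamin_c",
        "continuous",
        sd_units="1 SD ~ 17.6-21.5 umol/L depending on study population",
    )
    J = len(VITAMIN_C_LOCI)
    rel = np.linspace(0.8, 1.2, J)  # synthetic relative effect magnitudes
    eaf = np.linspace(0.20, 0.70, J)
    denom = float(np.sum(2.0 * rel**2 * eaf * (1 - eaf)))
    beta = rel * math.sqrt(VITAMIN_C_R2 / denom)
    for i, (snp, chrom, _gene) in enumerate(VITAMIN_C_LOCI):
        ea, oa = _ALLELE_PAIRS[i % len(_ALLELE_PAIRS)]
        se = math.sqrt(
            (1.0 - VITAMIN_C_R2) / (VITAMIN_C_GWAS_N * 2.0 * eaf[i] * (1 - eaf[i]))
        )
        panel.add(
            VariantAssociation(
                snp_id=snp,
                chrom=chrom,
                pos=1_000_000 * (i + 1),
                effect_allele=ea,
                other_allele=oa,
                eaf=float(eaf[i]),
                beta=float(beta[i]),
                se=se,
                pvalue=_two_sided_p(beta[i], se),
                n=VITAMIN_C_GWAS_N,
            )
        )
    return panel, VITAMIN_C_BLACKLIST


def simulate_outcome_for(
    exposure: StudyPanel,
    beta_causal: float,
    n_outcome: int,
    case_fraction: float,
    seed: int | tuple[int, ...] = 0,
    trait_name: str = "sim_outcome",
    pleiotropy: PleiotropyConfig | None = None,
) -> StudyPanel:
    """Draw a binary-outcome panel matched to an existing exposure panel,
    treating the exposure panel's betas as the true gamma. Useful for
    end-to-end demonstrations with the vitamin C fixture."""
    if not 0.0 < case_fraction < 1.0:
        raise SimulationError("case_fraction outside (0, 1)")
    rng = np.random.default_rng(seed)
    pl = pleiotropy or PleiotropyConfig()
    recs = list(exposure)
    J = len(recs)
    alpha = np.zeros(J)
    if pl.mode != "none" and pl.invalid_fraction > 0:
        n_invalid = int(round(pl.invalid_fraction * J))
        idx = rng.choice(J, size=n_invalid, replace=False)
        mean = pl.mean_alpha if pl.mode == "directional" else 0.0
        alpha[idx] = rng.normal(mean, pl.sd_alpha, n_invalid)
    n_cases = int(round(n_outcome * case_fraction))
    n_controls = n_outcome - n_cases
    outcome = StudyPanel(trait_name, "binary", n_cases=n_cases, n_controls=n_controls)
    for i, r in enumerate(recs):
        sy = math.sqrt(
            1.0
            / (n_outcome * case_fraction * (1 - case_fraction) * 2.0 * r.eaf * (1 - r.eaf))
        )
        Gam = beta_causal * r.beta + alpha[i]
        Gam_hat = float(rng.normal(Gam, sy))
        outcome.add(
            VariantAssociation(
                snp_id=r.snp_id,
                chrom=r.chrom,
                pos=r.pos,
                effect_allele=r.effect_allele,
                other_allele=r.other_allele,
                eaf=r.eaf,
                beta=Gam_hat,
                se=sy,
                pvalue=_two_sided_p(Gam_hat, sy),
                n=n_outcome,
                n_cases=n_cases,
                n_controls=n_controls,
            )
        )
    return outcome
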