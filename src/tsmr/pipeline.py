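"""Orchestration of a bi-directional analysis across outcome panels.

A run takes one exposure panel and several outcome panels, and for each
pair: selects instruments, substitutes proxies, aligns alleles, and runs
the full estimator battery. Forward and reverse analyses share this code
path — the direction only decides which panel supplies the instruments
(a reverse run's betas are the SD change in the continuous trait per
1-unit change in log odds of the disease trait). Failures are isolated
per pair so one malformed panel cannot abort a multi-outcome run.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .estimators import MREstimate, SuiteConfig, SuiteResult, run_estimator_suite
from .harmonize import (
    GWAS_P_THRESHOLD,
    PALINDROMIC_EAF_WINDOW,
    PROXY_R2_MIN,
    HarmonizedSet,
    LDReference,
    harmonize_panels,
)
from .sumstats import StudyPanel, read_summary_stats

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Configuration of one run (typically loaded from YAML)."""

    exposure: str
    outcomes: dict[str, str]  # outcome name -> panel path
    direction: str = "forward"  # forward | reverse | both (per-run label)
    p_threshold: float = GWAS_P_THRESHOLD
    r2_min: float = PROXY_R2_MIN
    palindromic_eaf_window: float = PALINDROMIC_EAF_WINDOW
    ld_reference: str | None = None
    blacklist: str | None = None  # newline-delimited snp_id file
    snp_exclusions: dict[str, list[str]] = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "mr_output"
    suite: SuiteConfig = field(default_factory=SuiteConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        suite_raw = raw.pop("suite", {})
        cfg = cls(**raw)
        cfg.suite = SuiteConfig(seed=cfg.seed, **suite_raw)
        return cfg


def _star_code(p: float | None) -> str:
    """Significance star coding: * p<0.05, ** p<0.01, *** p<0.001."""
    if p is None:
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def highlight_rules(
    suite: SuiteResult,
    presso_alpha: float = 0.01,
    het_alpha: float = 0.05,
) -> dict:
    """Machine-readable reporting flags for one pair's battery.

    ``prefer_outlier_corrected`` — the pleiotropy-robust (MR-PRESSO
    outlier-corrected / MR-Robust) estimates should be highlighted,
    because the PRESSO global test indicates horizontal pleiotropy
    (p < 0.01). ``prefer_weighted_median`` — the weighted-median
    estimate should be highlighted, because Cochran's Q indicates
    significant heterogeneity among the per-SNP estimates.
    """
    flags = {
        "prefer_outlier_corrected": False,
        "prefer_weighted_median": False,
        "stars": {},
    }
    presso = suite.get("presso")
    if presso is not None and presso.presso_global_p is not None:
        flags["prefer_outlier_corrected"] = presso.presso_global_p < presso_alpha
    ivw = suite.get("ivw_re")
    if ivw is not None and ivw.q_p is not None:
        flags["prefer_weighted_median"] = ivw.q_p < het_alpha
    for est in suite.estimates:
        flags["stars"][est.method] = _star_code(est.pvalue)
    return flags


@dataclass
class PairResult:
    outcome_name: str
    hset: HarmonizedSet | None
    suite: SuiteResult | None
    flags: dict | None
    error: str | None = None


@dataclass
class RunResult:
    pairs: list[PairResult]
    results: pd.DataFrame
    audit: pd.DataFrame
    output_dir: Path

    @property
    def failed(self) -> list[PairResult]:
        return [p for p in self.pairs if p.error is not None]


def analyze_pair(
    exposure: StudyPanel,
    outcome: StudyPanel,
    ld: LDReference | None,
    config: AnalysisConfig,
) -> tuple[HarmonizedSet, SuiteResult, dict]:
    """Harmonize one exposure-outcome pair and run the battery."""
    hset = harmonize_panels(
        exposure,
        outcome,
        ld,
        p_threshold=config.p_threshold,
        r2_min=config.r2_min,
        blacklist=_load_blacklist(config.blacklist),
        snp_exclusions=config.snp_exclusions.get(outcome.trait_name, []),
        palindromic_eaf_window=config.palindromic_eaf_window,
    )
    suite = run_estimator_suite(hset, config.suite)
    return hset, suite, highlight_rules(suite)


def _load_blacklist(path: str | None) -> frozenset[str]:
    if path is None:
        return frozenset()
    lines = Path(path).read_text().splitlines()
    return frozenset(s.strip() for s in lines if s.strip())


def run_direction(
    config: AnalysisConfig,
    exposure: StudyPanel | None = None,
    outcomes: dict[str, StudyPanel] | None = None,
    ld: LDReference | None = None,
) -> RunResult:
    """Run every exposure-outcome pair of a config and write reports.

    Panels may be passed in memory; otherwise they are read from the
    configured paths. Writes, under ``config.output_dir``:
    ``results.tsv`` (combined long-format table, one row per pair and
    method), per-pair ``<outcome>.tsv``, ``audit.tsv`` (every dropped or
    proxied variant with its reason), and ``run.json`` (config echo,
    seed, package version).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if exposure is None:
        exposure, _ = read_summary_stats(config.exposure)
    if outcomes is None:
        outcomes = {}
        for name, path in config.outcomes.items():
            panel, _ = read_summary_stats(path, trait_name=name)
            outcomes[name] = panel
    if ld is None and config.ld_reference:
        ld = LDReference.from_tsv(config.ld_reference)

    pairs: list[PairResult] = []
    frames: list[pd.DataFrame] = []
    audit_rows: list[dict] = []
    for name, panel in outcomes.items():
        try:
            hset, suite, flags = analyze_pair(exposure, panel, ld, config)
        except Exception as exc:  # isolate pair failures
            logger.error("pair %s -> %s failed: %s", exposure.trait_name, name, exc)
            pairs.append(PairResult(name, None, None, None, error=str(exc)))
            continue
        pairs.append(PairResult(name, hset, suite, flags))
        frame = suite.to_frame()
        frame["prefer_outlier_corrected"] = flags["prefer_outlier_corrected"]
        frame["prefer_weighted_median"] = flags["prefer_weighted_median"]
        frame["stars"] = frame["method"].map(flags["stars"]).fillna("")
        frames.append(frame)
        frame.to_csv(outdir / f"{_safe(name)}.tsv", sep="\t", index=False)
        for inst in list(hset.instruments) + list(hset.audit):
            audit_rows.append(
                {
                    "exposure": hset.exposure_name,
                    "outcome": name,
                    "snp": inst.snp_id,
                    "proxy_of": inst.proxy_of,
                    "action": inst.action,
                }
            )

    results = (
        pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    )
    audit = pd.DataFrame(audit_rows, columns=["exposure", "outcome", "snp", "proxy_of", "action"])
    results.to_csv(outdir / "results.tsv", sep="\t", index=False)
    audit.to_csv(outdir / "audit.tsv", sep="\t", index=False)
    (outdir / "run.json").write_text(
        json.dumps(
            {
                "direction": config.direction,
                "exposure": exposure.trait_name,
                "outcomes": list(outcomes),
                "p_threshold": config.p_threshold,
                "r2_min": config.r2_min,
                "seed": config.seed,
                "version": __version__,
                "failures": {p.outcome_name: p.error for p in pairs if p.error},
            },
            indent=2,
        )
    )
    return RunResult(pairs, results, audit, outdir)


def _safe(name: str) -> str:
    return "".join(c if c.isalnum() or c in "-_." else "_" for c in name)
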