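"""Instrument selection, LD proxy substitution and allele alignment.

The two-sample design needs each variant's effect on the exposure
(``gamma``, SD units) and on the outcome (``Gamma``, log-OR units)
expressed per copy of the *same* allele. This module selects
genome-wide-significant instruments from the exposure panel, substitutes
an in-phase linkage-disequilibrium proxy when an instrument is absent
from the outcome panel, and aligns effect alleles, flipping signs and
frequencies or complementing strands as needed. Palindromic variants
(A/T or C/G) whose allele frequency is close to 0.5 cannot be
strand-resolved and are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sumstats import StudyPanel, VariantAssociation

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default significance threshold for instrument selection (strict "<")
GWAS_P_THRESHOLD = 5e-8
#: default minimum squared LD correlation for a proxy (strict ">")
PROXY_R2_MIN = 0.8
#: palindromic variants with |eaf - 0.5| <= window are dropped
PALINDROMIC_EAF_WINDOW = 0.08


class HarmonizationError(ValueError):
    """Base class for harmonization failures."""


class NoInstrumentsError(HarmonizationError):
    """No variant survives the significance threshold and blacklist."""


class AlleleMismatchError(HarmonizationError):
    """Exposure and outcome alleles cannot be reconciled, even by strand flip."""


@dataclass
class LDReference:
    """Pairwise signed LD correlations among nearby variants.

    Stored symmetrically: ``r(a, b) == r(b, a)`` and ``r(a, a) == 1``.
    The sign of r carries phase: r > 0 means the two variants' stored
    effect alleles co-occur on the same haplotype.
    """

    sample_n: int = 503
    _table: dict[str, dict[str, float]] = field(default_factory=dict)

    @classmethod
    def from_entries(
        cls, entries: Iterable[tuple[str, str, float]], sample_n: int = 503
    ) -> "LDReference":
        ld = cls(sample_n=sample_n)
        for a, b, r in entries:
            ld.add(a, b, r)
        return ld

    @classmethod
    def from_tsv(cls, path: str | Path, sample_n: int = 503) -> "LDReference":
        """Read a reference from a TSV with columns SNP_A, SNP_B, R."""
        df = pd.read_csv(path, sep="\t", dtype={"SNP_A": str, "SNP_B": str})
        for col in ("SNP_A", "SNP_B", "R"):
            if col not in df.columns:
                raise HarmonizationError(f"LD reference {path}: missing column {col}")
        return cls.from_entries(
            zip(df["SNP_A"], df["SNP_B"], df["R"].astype(float)), sample_n=sample_n
        )

    def add(self, a: str, b: str, r: float) -> None:
        if not -1.0 <= r <= 1.0:
            raise HarmonizationError(f"LD r({a},{b})={r} outside [-1, 1]")
        self._table.setdefault(a, {})[b] = r
        self._table.setdefault(b, {})[a] = r

    def knows(self, snp: str) -> bool:
        return snp in self._table

    def r(self, a: str, b: str) -> float | None:
        if a == b:
            return 1.0
        return self._table.get(a, {}).get(b)

    def neighbors(self, snp: str) -> dict[str, float]:
        return dict(self._table.get(snp, {}))

    def to_tsv(self, path: str | Path) -> Path:
        rows, seen = [], set()
        for a, nbrs in self._table.items():
            for b, r in nbrs.items():
                if (b, a) in seen:
                    continue
                seen.add((a, b))
                rows.append((a, b, r))
        pd.DataFrame(rows, columns=["SNP_A", "SNP_B", "R"]).to_csv(
            path, sep="\t", index=False
        )
        return Path(path)


@dataclass(frozen=True)
class HarmonizedInstrument:
    """An exposure-outcome variant pair with alleles aligned.

    ``beta_exp``/``se_exp`` are the SNP-exposure association (gamma and
    its SE), ``beta_out``/``se_out`` the SNP-outcome association (Gamma
    and its SE), both per copy of the exposure panel's effect allele.
    """

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float
    eaf_out: float
    palindromic: bool
    action: str  # kept | flipped | proxied | dropped_palindromic | dropped_no_proxy
    proxy_of: str | None = None

    def __post_init__(self) -> None:
        if self.action in ("kept", "flipped", "proxied"):
            if not (self.se_exp > 0 and self.se_out > 0):
                raise HarmonizationError(f"{self.snp_id}: non-positive SE")


@dataclass
class HarmonizedSet:
    """Analysis-ready instruments for one exposure-outcome pair."""

    exposure_name: str
    outcome_name: str
    instruments: list[HarmonizedInstrument] = field(default_factory=list)
    audit: list[HarmonizedInstrument] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.instruments)

    def __iter__(self):
        return iter(self.instruments)

    @property
    def snp_ids(self) -> list[str]:
        return [i.snp_id for i in self.instruments]

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        g = np.array([i.beta_exp for i in self.instruments])
        sx = np.array([i.se_exp for i in self.instruments])
        G = np.array([i.beta_out for i in self.instruments])
        sy = np.array([i.se_out for i in self.instruments])
        return g, sx, G, sy

    def without(self, snp_ids: Iterable[str]) -> "HarmonizedSet":
        drop = set(snp_ids)
        return HarmonizedSet(
            self.exposure_name,
            self.outcome_name,
            [i for i in self.instruments if i.snp_id not in drop],
            list(self.audit),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "SNP": i.snp_id,
                    "PROXY_OF": i.proxy_of,
                    "BETA_EXP": i.beta_exp,
                    "SE_EXP": i.se_exp,
                    "BETA_OUT": i.beta_out,
                    "SE_OUT": i.se_out,
                    "EAF_EXP": i.eaf_exp,
                    "EAF_OUT": i.eaf_out,
                    "PALINDROMIC": i.palindromic,
                    "ACTION": i.action,
                }
                for i in list(self.instruments) + list(self.audit)
            ]
        )


def select_instruments(
    panel: StudyPanel,
    p_threshold: float = GWAS_P_THRESHOLD,
    blacklist: Iterable[str] = (),
) -> list[str]:
    """Variants with ``pvalue < p_threshold`` (strict) not in ``blacklist``.

    Input order is preserved. Raises :class:`NoInstrumentsError` when
    nothing survives.
    """
    if not 0.0 < p_threshold < 1.0:
        raise HarmonizationError(f"p_threshold {p_threshold} outside (0, 1)")
    bl = set(blacklist)
    out = [r.snp_id for r in panel if r.pvalue < p_threshold and r.snp_id not in bl]
    if not out:
        raise NoInstrumentsError(
            f"no instruments for {panel.trait_name!r} at p < {p_threshold:g}"
        )
    return out


def find_proxy(
    target: str,
    candidates: StudyPanel,
    ld: LDReference,
    r2_min: float = PROXY_R2_MIN,
) -> tuple[str, float] | None:
    """Best in-phase LD proxy for ``target`` present in ``candidates``.

    Returns ``(proxy snp_id, signed r)`` for the candidate with maximal
    r² strictly above ``r2_min`` (ties broken by lexicographic snp_id),
    or None if no candidate qualifies or the target is unknown to the
    LD reference.
    """
    if not 0.0 < r2_min < 1.0:
        raise HarmonizationError(f"r2_min {r2_min} outside (0, 1)")
    if not ld.knows(target):
        return None
    best: tuple[float, str, float] | None = None  # (r2, snp, r)
    for snp, r in ld.neighbors(target).items():
        if snp == target or snp not in candidates:
            continue
        r2 = r * r
        if r2 <= r2_min:
            continue
        if best is None or r2 > best[0] or (r2 == best[0] and snp < best[1]):
            best = (r2, snp, r)
    if best is None:
        return None
    return best[1], best[2]


def _is_palindromic(ea: str, oa: str) -> bool:
    return COMPLEMENT[ea] == oa


def align_alleles(
    exp_rec: VariantAssociation,
    out_rec: VariantAssociation,
    palindromic_eaf_window: float = PALINDROMIC_EAF_WINDOW,
) -> HarmonizedInstrument:
    """Express the outcome association per copy of the exposure's effect allele.

    Non-palindromic pairs: identical orientation is kept; a swapped
    allele pair negates the outcome beta and complements its frequency;
    allele pairs matching only after strand complement are complemented
    first. Palindromic pairs with allele frequency within
    ``palindromic_eaf_window`` of 0.5 on either panel are dropped as
    strand-unresolvable; outside the window the strand is inferred from
    frequency concordance.
    """
    e_ea, e_oa = exp_rec.effect_allele, exp_rec.other_allele
    o_ea, o_oa = out_rec.effect_allele, out_rec.other_allele
    palindromic = _is_palindromic(e_ea, e_oa)

    def build(action: str, beta_out: float, eaf_out: float) -> HarmonizedInstrument:
        return HarmonizedInstrument(
            snp_id=exp_rec.snp_id,
            beta_exp=exp_rec.beta,
            se_exp=exp_rec.se,
            beta_out=beta_out,
            se_out=out_rec.se,
            eaf_exp=exp_rec.eaf,
            eaf_out=eaf_out,
            palindromic=palindromic,
            action=action,
        )

    if palindromic:
        if not _is_palindromic(o_ea, o_oa) or {o_ea, o_oa} != {e_ea, e_oa}:
            raise AlleleMismatchError(
                f"{exp_rec.snp_id}: alleles {e_ea}/{e_oa} vs {o_ea}/{o_oa} irreconcilable"
            )
        # small epsilon keeps the boundary (e.g. eaf 0.42 with window
        # 0.08) inside the drop region despite float representation
        ambiguous = (
            abs(exp_rec.eaf - 0.5) <= palindromic_eaf_window + 1e-12
            or abs(out_rec.eaf - 0.5) <= palindromic_eaf_window + 1e-12
        )
        if ambiguous:
            return build("dropped_palindromic", out_rec.beta, out_rec.eaf)
        # nominal orientation from the allele letters, then strand check
        # from frequency concordance: a palindromic strand flip looks
        # like an allele swap, so discordant frequencies flip once more.
        flipped = o_ea == e_oa
        beta = -out_rec.beta if flipped else out_rec.beta
        eaf = 1.0 - out_rec.eaf if flipped else out_rec.eaf
        if (exp_rec.eaf < 0.5) != (eaf < 0.5):
            flipped = not flipped
            beta, eaf = -beta, 1.0 - eaf
        return build("flipped" if flipped else "kept", beta, eaf)

    # non-palindromic: try direct, swapped, then strand-complemented
    if (o_ea, o_oa) == (e_ea, e_oa):
        return build("kept", out_rec.beta, out_rec.eaf)
    if (o_ea, o_oa) == (e_oa, e_ea):
        return build("flipped", -out_rec.beta, 1.0 - out_rec.eaf)
    c_ea, c_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
    if (c_ea, c_oa) == (e_ea, e_oa):
        return build("kept", out_rec.beta, out_rec.eaf)
    if (c_ea, c_oa) == (e_oa, e_ea):
        return build("flipped", -out_rec.beta, 1.0 - out_rec.eaf)
    raise AlleleMismatchError(
        f"{exp_rec.snp_id}: alleles {e_ea}/{e_oa} vs {o_ea}/{o_oa} irreconcilable"
    )


def harmonize_panels(
    exposure: StudyPanel,
    outcome: StudyPanel,
    ld: LDReference | None = None,
    *,
    p_threshold: float = GWAS_P_THRESHOLD,
    r2_min: float = PROXY_R2_MIN,
    blacklist: Iterable[str] = (),
    snp_exclusions: Iterable[str] = (),
    palindromic_eaf_window: float = PALINDROMIC_EAF_WINDOW,
) -> HarmonizedSet:
    """Select, proxy and align: the full harmonization pass for one pair.

    ``blacklist`` removes known-pleiotropic exposure instruments before
    selection; ``snp_exclusions`` removes named instruments for this
    specific outcome (sensitivity re-runs). Dropped variants are kept in
    the set's audit with their reason encoded in ``action``.
    """
    selected = select_instruments(
        exposure, p_threshold, set(blacklist) | set(snp_exclusions)
    )
    hset = HarmonizedSet(exposure.trait_name, outcome.trait_name)
    for snp in selected:
        exp_rec = exposure[snp]
        if snp in outcome:
            inst = align_alleles(exp_rec, outcome[snp], palindromic_eaf_window)
            if inst.action == "dropped_palindromic":
                hset.audit.append(inst)
            else:
                hset.instruments.append(inst)
            continue
        proxy = find_proxy(snp, outcome, ld, r2_min) if ld is not None else None
        if proxy is None:
            hset.audit.append(
                HarmonizedInstrument(
                    snp_id=snp,
                    beta_exp=exp_rec.beta,
                    se_exp=exp_rec.se,
                    beta_out=float("nan"),
                    se_out=float("nan"),
                    eaf_exp=exp_rec.eaf,
                    eaf_out=float("nan"),
                    palindromic=_is_palindromic(
                        exp_rec.effect_allele, exp_rec.other_allele
                    ),
                    action="dropped_no_proxy",
                )
            )
            continue
        proxy_id, r = proxy
        prec = outcome[proxy_id]
        sign = 1.0 if r > 0 else -1.0
        # in-phase convention: sign(r) relates the proxy's effect allele
        # to the original's effect allele on the same haplotype.
        hset.instruments.append(
            HarmonizedInstrument(
                snp_id=proxy_id,
                proxy_of=snp,
                beta_exp=exp_rec.beta,
                se_exp=exp_rec.se,
                beta_out=sign * prec.beta,
                se_out=prec.se,
                eaf_exp=exp_rec.eaf,
                eaf_out=prec.eaf if sign > 0 else 1.0 - prec.eaf,
                palindromic=False,
                action="proxied",
            )
        )
    return hset


def estimate_variance_explained(
    instruments: Iterable[tuple[float, float] | VariantAssociation],
) -> float:
    """Trait variance explained by independent SNPs on a standardized scale.

    For a trait standardized to unit variance, each biallelic SNP with
    per-allele effect beta and effect-allele frequency f contributes
    2 f (1 - f) beta^2; the total is the instrument R².
    """
    total = 0.0
    for item in instruments:
        if isinstance(item, VariantAssociation):
            beta, eaf = item.beta, item.eaf
        else:
            beta, eaf = item
        if not 0.0 < eaf < 1.0:
            raise HarmonizationError(f"eaf {eaf} outside (0, 1)")
        total += 2.0 * beta * beta * eaf * (1.0 - eaf)
    return total


def greedy_ld_prune(
    snp_ids: Sequence[str], ld: LDReference, r2_max: float = 0.01
) -> list[str]:
    """Greedy independence pruning: keep each variant whose r² with every
    already-kept variant is below ``r2_max``. Input order gives priority."""
    kept: list[str] = []
    for snp in snp_ids:
        ok = True
        for prev in kept:
            r = ld.r(snp, prev)
            if r is not None and r * r >= r2_max:
                ok = False
                break
        if ok:
            kept.append(snp)
    return kept
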