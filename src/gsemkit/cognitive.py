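"""Model builders for the cognitive-domain genomic SEM analyses.

Covers the correlated three-dimension confirmatory model (reaction time RT,
fluid reasoning Gf, crystallized knowledge Gc), the one-factor language
model, the extension with educational attainment (EA) and the language
factor, the Cholesky GWAS-by-subtraction re-parameterization with
orthogonal factors RT -> Gf_u -> Gc_u -> NonCog, and single-external-trait
correlation models. Factor labels carry a trailing marker to avoid
colliding with indicator names (RTg, EAg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sem import (UNIT_LOADING, UNIT_VARIANCE, FitResult, ModelSpec,
                  standardize)

__all__ = ["CognitiveBattery", "build_cfa", "build_language_factor",
           "build_extended", "build_subtraction", "build_external",
           "variance_decomposition", "noncog_share"]

#: Cholesky factor names in decomposition order (basic to least basic)
SUBTRACTION_FACTORS = ["RTg", "Gf_u", "Gc_u", "NonCog"]


@dataclass
class CognitiveBattery:
    """Mapping from model roles to trait labels in a covariance estimate.

    ``gf_indicators`` and ``gc_indicators`` exclude the cross-loading
    indicator, which loads on both Gf and Gc (verbal-numerical reasoning in
    the reference battery).
    """

    rt: str = "RT"
    gf_indicators: list[str] = field(default_factory=lambda: ["matrix", "tower", "TMTB"])
    gc_indicators: list[str] = field(default_factory=lambda: ["VocSyn", "VocPic"])
    cross_loading: str | None = "VNR"
    language: str | None = "LANG"
    language_tests: list[str] = field(default_factory=lambda: [
        "word_reading", "nonword_reading", "phoneme_awareness", "spelling"])
    ea: str = "EA"
    # unit-loading anchors for GWAS-mode identification
    gf_anchor: str = "matrix"
    gc_anchor: str = "VocSyn"

    def __post_init__(self) -> None:
        for role, traits in (("Gf-indicator", self.gf_indicators),
                             ("Gc-indicator", self.gc_indicators)):
            if len(traits) < 2:
                raise ValueError(f"missing trait for role {role}: need at "
                                 f"least 2 indicators, got {traits}")
        if not self.rt:
            raise ValueError("missing trait for role RT")
        if not self.ea:
            raise ValueError("missing trait for role EA")

    def gf_all(self) -> list[str]:
        out = list(self.gf_indicators)
        if self.cross_loading:
            out.append(self.cross_loading)
        return out

    def gc_all(self) -> list[str]:
        out = []
        if self.cross_loading:
            out.append(self.cross_loading)
        out.extend(self.gc_indicators)
        return out

    def cognitive_traits(self) -> list[str]:
        return [self.rt] + self.gf_indicators + ([self.cross_loading] if
                                                 self.cross_loading else []) \
            + self.gc_indicators


def build_cfa(battery: CognitiveBattery) -> ModelSpec:
    """Correlated RT/Gf/Gc confirmatory model (unit-variance identified).

    RT is directly indexed by its single measure: the latent RTg has one
    free loading on the RT trait whose residual is fixed to 0, so RTg is the
    trait's own genetic component. All three factor correlations are free.
    """
    spec = ModelSpec(statements=[], latents=[], identification=UNIT_VARIANCE)
    spec.add("loading", "RTg", battery.rt)
    spec.add("covariance", battery.rt, battery.rt, fixed=0.0)
    for ind in battery.gf_all():
        spec.add("loading", "Gf", ind)
    for ind in battery.gc_all():
        spec.add("loading", "Gc", ind)
    for f1, f2 in (("RTg", "Gf"), ("RTg", "Gc"), ("Gf", "Gc")):
        spec.add("covariance", f1, f2)
    return spec


def build_language_factor(traits: list[str], gwas_mode: bool = False,
                          anchor: str | None = None) -> ModelSpec:
    """One-factor model of the four language tests.

    ``gwas_mode`` switches to unit-loading identification with the anchor's
    unstandardized loading fixed to 1 (nonword reading by convention, i.e.
    the second trait when no anchor is named) and the factor variance free.
    """
    if len(traits) != 4:
        raise ValueError(f"language factor expects 4 traits, got {len(traits)}")
    mode = UNIT_LOADING if gwas_mode else UNIT_VARIANCE
    spec = ModelSpec(statements=[], latents=[], identification=mode)
    anchor = anchor or traits[1]
    for t in traits:
        if gwas_mode and t == anchor:
            spec.add("loading", "LANGg", t, fixed=1.0)
        else:
            spec.add("loading", "LANGg", t)
    return spec


def build_extended(battery: CognitiveBattery, gwas_mode: bool = False
                   ) -> ModelSpec:
    """Correlated model extended with the language factor trait and EA.

    The language summary statistic loads on Gc and (to absorb any residual
    relation) on Gf; EA enters as a single-indicator factor correlated with
    RT, Gf and Gc. In GWAS mode the Gf -> language path is dropped and the
    anchors (Gf and Gc indicators named by the battery) are fixed to 1
    under unit-loading identification.
    """
    if not battery.language:
        raise ValueError("missing trait for role language-indicator")
    mode = UNIT_LOADING if gwas_mode else UNIT_VARIANCE
    spec = ModelSpec(statements=[], latents=[], identification=mode)
    anchor = {battery.gf_anchor: "Gf", battery.gc_anchor: "Gc"} if gwas_mode else {}

    def loading(fac: str, ind: str) -> None:
        spec.add("loading", fac, ind,
                 fixed=1.0 if anchor.get(ind) == fac else None)

    loading("RTg", battery.rt)
    spec.add("covariance", battery.rt, battery.rt, fixed=0.0)
    for ind in battery.gf_all():
        loading("Gf", ind)
    if not gwas_mode:
        loading("Gf", battery.language)
    for ind in battery.gc_all():
        loading("Gc", ind)
    loading("Gc", battery.language)
    loading("EAg", battery.ea)
    spec.add("covariance", battery.ea, battery.ea, fixed=0.0)
    factors = ["RTg", "Gf", "Gc", "EAg"]
    for i, f1 in enumerate(factors):
        for f2 in factors[i + 1:]:
            spec.add("covariance", f1, f2)
    return spec


def build_subtraction(battery: CognitiveBattery, gwas_mode: bool = False
                      ) -> ModelSpec:
    """Cholesky GWAS-by-subtraction model with orthogonal factors.

    Factors enter in order RT -> Gf_u -> Gc_u -> NonCog (basic before
    higher-order): RT loads on every indicator, Gf_u on everything past the
    RT measure, Gc_u on the Gc-stream indicators (including the
    cross-loading indicator) and EA, and NonCog only on EA. All factor
    covariances are fixed to 0 and the RT and EA residuals are fixed to 0,
    so NonCog is exactly the EA genetic variance unshared with the
    cognitive factors. GWAS mode fixes the unit-loading anchors: the RT
    trait for RTg, the Gf anchor for Gf_u, the Gc anchor for Gc_u and EA
    for NonCog.
    """
    if not battery.language:
        raise ValueError("missing trait for role language-indicator")
    mode = UNIT_LOADING if gwas_mode else UNIT_VARIANCE
    spec = ModelSpec(statements=[], latents=[], identification=mode)
    anchors = {"RTg": battery.rt, "Gf_u": battery.gf_anchor,
               "Gc_u": battery.gc_anchor, "NonCog": battery.ea} if gwas_mode else {}

    gf_stream = battery.gf_all()
    gc_stream = battery.gc_all() + [battery.language]
    targets = {
        "RTg": [battery.rt] + gf_stream
               + [t for t in gc_stream if t not in gf_stream] + [battery.ea],
        "Gf_u": gf_stream + [t for t in gc_stream if t not in gf_stream]
                + [battery.ea],
        "Gc_u": gc_stream + [battery.ea],
        "NonCog": [battery.ea],
    }
    for fac in SUBTRACTION_FACTORS:
        for ind in targets[fac]:
            spec.add("loading", fac, ind,
                     fixed=1.0 if anchors.get(fac) == ind else None)
    spec.add("covariance", battery.rt, battery.rt, fixed=0.0)
    spec.add("covariance", battery.ea, battery.ea, fixed=0.0)
    for i, f1 in enumerate(SUBTRACTION_FACTORS):
        for f2 in SUBTRACTION_FACTORS[i + 1:]:
            spec.add("covariance", f1, f2, fixed=0.0)
    return spec


def build_external(battery: CognitiveBattery, external_trait: str,
                   gwas_mode: bool = False) -> ModelSpec:
    """Subtraction model plus one external trait correlated with all factors.

    Adds exactly five free parameters: the external trait's variance and
    its covariance with each of RT, Gf_u, Gc_u and NonCog. External traits
    are modeled one at a time.
    """
    spec = build_subtraction(battery, gwas_mode=gwas_mode)
    spec.add("covariance", external_trait, external_trait)
    for fac in SUBTRACTION_FACTORS:
        spec.add("covariance", external_trait, fac)
    return spec


def noncog_share(cognitive_loadings) -> float:
    """Percent of EA genetic variance attributable to NonCog.

    ``cognitive_loadings`` is either the single combined standardized
    cognitive-pathway loading or the vector of standardized EA loadings on
    the cognitive factors; with the EA residual fixed to 0 the NonCog share
    is 1 minus the summed squared cognitive loadings.
    """
    lam = np.atleast_1d(np.asarray(cognitive_loadings, dtype=float))
    share = 1.0 - float(np.sum(lam ** 2))
    return 100.0 * share


def variance_decomposition(result: FitResult, indicator: str) -> dict[str, float]:
    """Per-factor shares (percent) of an indicator's genetic variance.

    Shares are squared standardized loadings; any residual variance is
    reported under ``"residual"`` so the shares always sum to 100.
    """
    std = standardize(result)
    shares: dict[str, float] = {}
    for _, row in std.iterrows():
        label = row["parameter"]
        if label.endswith(f"=:{indicator}"):
            factor = label.split("=:", 1)[0]
            shares[factor] = 100.0 * float(row["std_estimate"]) ** 2
        elif label == f"{indicator}~~{indicator}":
            resid = 100.0 * float(row["std_estimate"])
            if abs(resid) > 1e-10:
                shares["residual"] = resid
    return shares
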