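"""Synthetic inputs with the statistical structure the analyses assume.

Generators for (a) palmitate MID tables with known (D, g), (b) community
bin-abundance and gene-expression count tables with planted group effects,
(c) serum short-chain fatty-acid tables with a planted acetate fold change,
and (d) desk-scale toy metabolic models whose optima are known in closed
form. Every generator is a pure function of its spec including the seed.

Default study conditions mirror the emulated experiment: 7 + 7 samples
(N = 14 cohort), Bacteroidetes taxa up and Enterococcaceae taxa down under
ethanol, acs (AMP acetyl-CoA synthetase) expression up against a stable
rpoA reference, a 4x acetate group effect among eight SCFAs, and a
cometabolism toy model that cannot grow on acetate alone but grows faster
on glycerol + acetate than on glycerol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .compositional import FeatureTable
from .gem import MetabolicModel, Metabolite, Reaction
from .isa import PrecursorUnit, simulate_analyte_mid

__all__ = [
    "MidSimSpec",
    "TaxonSpec",
    "CommunitySimSpec",
    "ToyGemSpec",
    "ToyGem",
    "SCFA_ANALYTES",
    "generate_mid_dataset",
    "generate_count_tables",
    "generate_scfa_table",
    "generate_toy_gem",
]

SCFA_ANALYTES = (
    "acetate",
    "butyrate",
    "caproate",
    "heptanoate",
    "isobutyrate",
    "isovalerate",
    "propionate",
    "valerate",
)

# baseline serum concentrations (uM-scale, arbitrary but realistic ordering:
# acetate dominates, long/branched chains are trace)
_SCFA_BASELINE = {
    "acetate": 200.0,
    "butyrate": 20.0,
    "caproate": 2.0,
    "heptanoate": 1.0,
    "isobutyrate": 4.0,
    "isovalerate": 5.0,
    "propionate": 30.0,
    "valerate": 3.0,
}


@dataclass(frozen=True)
class MidSimSpec:
    """Conditions for a labelled-analyte MID dataset."""

    formula: str = "C16"
    n_units: int = 8
    D_true: float = 0.27
    g_true: float = 0.6
    noise_sd: float = 0.003
    n_samples: int = 3
    seed: int = 0
    unit: PrecursorUnit = field(default_factory=PrecursorUnit)
    tissue: str = "cecum"

    def __post_init__(self) -> None:
        if not (0.0 <= self.D_true <= 1.0 and 0.0 <= self.g_true <= 1.0):
            raise ValueError("D_true and g_true must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


class TaxonSpec(NamedTuple):
    name: str
    phylum: str
    family: str
    base_log_abundance: float  # natural-log relative weight
    effect_log2: float  # planted between-group log2 fold change


_DEFAULT_TAXA = (
    TaxonSpec("bin.135", "Bacteroidetes", "Bacteroidaceae", 2.0, 1.0),
    TaxonSpec("bin.412", "Bacteroidetes", "Bacteroidaceae", 1.5, 1.0),
    TaxonSpec("bin.480", "Bacteroidetes", "Tannerellaceae", 1.0, 1.0),
    TaxonSpec("bin.201", "Firmicutes", "Enterococcaceae", 1.5, -1.0),
    TaxonSpec("bin.202", "Firmicutes", "Enterococcaceae", 1.0, -1.0),
    TaxonSpec("bin.300", "Firmicutes", "Lachnospiraceae", 2.0, 0.0),
    TaxonSpec("bin.301", "Firmicutes", "Ruminococcaceae", 1.8, 0.0),
    TaxonSpec("bin.400", "Proteobacteria", "Enterobacteriaceae", 0.5, 0.0),
)

# per-bin genes on the expression table: (symbol, length bp, baseline ln level)
_GENES = (
    ("rpoA", 1000, 3.0),
    ("adh", 1100, 2.0),
    ("acs", 1950, 2.5),
)


@dataclass(frozen=True)
class CommunitySimSpec:
    """Conditions for community abundance/expression count tables."""

    n_per_group: int = 7
    taxa: tuple[TaxonSpec, ...] = _DEFAULT_TAXA
    depth_range: tuple[int, int] = (20_000, 60_000)
    dispersion: float = 0.5  # sd of per-sample ln-abundance noise
    acs_effect_log2: float = 1.5  # planted acs upregulation in the ethanol group
    groups: tuple[str, str] = ("control", "ethanol")
    # annotation sets the downstream log-ratio contrast will aggregate
    contrasts: tuple[tuple[str, str], ...] = (
        ("phylum", "Bacteroidetes"),
        ("family", "Enterococcaceae"),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.depth_range[0] <= 0 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("depth_range must be positive and ordered")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for column, label in self.contrasts:
            n = sum(1 for t in self.taxa if getattr(t, column) == label)
            if n < 2:
                raise ValueError(
                    f"contrasted label set {label!r} ({column}) has fewer than 2 taxa"
                )


@dataclass(frozen=True)
class ToyGemSpec:
    template: str = "cometabolism"
    perturbations: dict | None = None  # reaction id -> (lb, ub)
    seed: int = 0


class ToyGem(NamedTuple):
    model: MetabolicModel
    analytic: dict  # closed-form reference values for the unperturbed fixture


def generate_mid_dataset(spec: MidSimSpec) -> pd.DataFrame:
    """Per-sample MIDs around the forward model, Gaussian channel noise,
    clipped at zero and renormalised. Columns: sample, tissue, M0..Mn."""
    base = simulate_analyte_mid(
        spec.D_true, spec.g_true, spec.unit, spec.n_units, spec.formula
    ).fractions
    rng = np.random.default_rng(spec.seed)
    noisy = base + rng.normal(0.0, spec.noise_sd, size=(spec.n_samples, base.size))
    clipped_fraction = np.mean(noisy < 0)
    if clipped_fraction > 0.5:
        raise ValueError(
            f"noise_sd={spec.noise_sd} drives {clipped_fraction:.0%} of MID entries "
            "below zero; use a smaller noise_sd"
        )
    noisy = np.clip(noisy, 0.0, None)
    noisy /= noisy.sum(axis=1, keepdims=True)
    df = pd.DataFrame(noisy, columns=[f"M{k}" for k in range(base.size)])
    df.insert(0, "tissue", spec.tissue)
    df.insert(0, "sample", [f"s{i + 1:02d}" for i in range(spec.n_samples)])
    return df


def _sample_ids(n: int) -> list[str]:
    return [f"s{i + 1:02d}" for i in range(n)]


def generate_count_tables(
    spec: CommunitySimSpec,
) -> tuple[FeatureTable, FeatureTable, pd.DataFrame]:
    """(bin abundance table, per-bin gene expression table, sample metadata).

    Log-normal latent abundances (baseline + group effect + dispersion
    noise) are converted to counts by multinomial sampling at a per-sample
    depth, reproducing the depth-confounded, zero-inflated structure of
    real bin tables. The expression table plants an effect only on ``acs``
    (and only in Bacteroidetes bins, which are the ones carrying an
    acetate-to-acetyl-CoA route); ``rpoA`` and ``adh`` are null features.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_group
    samples = _sample_ids(2 * n)
    group = np.array([spec.groups[0]] * n + [spec.groups[1]] * n)
    is_treated = (group == spec.groups[1]).astype(float)

    meta = pd.DataFrame({"group": group}, index=pd.Index(samples, name="sample"))

    taxa = list(spec.taxa)
    base = np.array([t.base_log_abundance for t in taxa])
    effect = np.array([t.effect_log2 for t in taxa]) * np.log(2.0)
    latent = (
        base[None, :]
        + is_treated[:, None] * effect[None, :]
        + rng.normal(0.0, spec.dispersion, size=(2 * n, len(taxa)))
    )
    probs = np.exp(latent)
    probs /= probs.sum(axis=1, keepdims=True)
    depths = rng.integers(spec.depth_range[0], spec.depth_range[1] + 1, size=2 * n)
    abundance = np.vstack([rng.multinomial(d, p) for d, p in zip(depths, probs)])
    abundance_table = FeatureTable(
        counts=pd.DataFrame(
            abundance, index=meta.index, columns=[t.name for t in taxa]
        ),
        feature_meta=pd.DataFrame(
            {"phylum": [t.phylum for t in taxa], "family": [t.family for t in taxa]},
            index=pd.Index([t.name for t in taxa], name="feature"),
        ),
        sample_meta=meta,
    )

    # expression: bins x genes; acs only in Bacteroidetes bins
    features, gene_of, bin_of, lengths, e_base, e_effect = [], [], [], [], [], []
    for t_idx, taxon in enumerate(taxa):
        for symbol, length, level in _GENES:
            if symbol == "acs" and taxon.phylum != "Bacteroidetes":
                continue
            features.append(f"{taxon.name}|{symbol}")
            gene_of.append(symbol)
            bin_of.append(taxon.name)
            lengths.append(length)
            e_base.append(base[t_idx] + level)
            e_effect.append(
                effect[t_idx]
                + (np.log(2.0) * spec.acs_effect_log2 if symbol == "acs" else 0.0)
            )
    e_base = np.array(e_base)
    e_effect = np.array(e_effect)
    e_latent = (
        e_base[None, :]
        + is_treated[:, None] * e_effect[None, :]
        + rng.normal(0.0, spec.dispersion, size=(2 * n, len(features)))
    )
    e_probs = np.exp(e_latent)
    e_probs /= e_probs.sum(axis=1, keepdims=True)
    e_depths = rng.integers(spec.depth_range[0], spec.depth_range[1] + 1, size=2 * n)
    expr = np.vstack([rng.multinomial(d, p) for d, p in zip(e_depths, e_probs)])
    taxon_by_name = {t.name: t for t in taxa}
    expression_table = FeatureTable(
        counts=pd.DataFrame(expr, index=meta.index, columns=features),
        feature_meta=pd.DataFrame(
            {
                "gene": gene_of,
                "bin": bin_of,
                "phylum": [taxon_by_name[b].phylum for b in bin_of],
                "family": [taxon_by_name[b].family for b in bin_of],
                "length_bp": lengths,
            },
            index=pd.Index(features, name="feature"),
        ),
        sample_meta=meta,
    )
    return abundance_table, expression_table, meta


def generate_scfa_table(
    n_per_group: int = 7,
    acetate_fold: float = 4.0,
    noise_cv: float = 0.2,
    seed: int = 0,
    groups: tuple[str, str] = ("control", "ethanol"),
) -> pd.DataFrame:
    """Serum SCFA concentration table with a planted acetate group effect.

    Concentrations are log-normal around per-analyte baselines; only
    acetate's mean is multiplied by ``acetate_fold`` in the second group.
    """
    if acetate_fold <= 0:
        raise ValueError("acetate_fold must be > 0")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if n_per_group == 1:
        warnings.warn(
            "n_per_group=1: table generated but group tests are impossible",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    group = [groups[0]] * n_per_group + [groups[1]] * n_per_group
    # log-normal with mean exactly at baseline: ln-mean = ln(m) - s^2/2
    sigma = np.sqrt(np.log(1.0 + noise_cv**2))
    data = {"sample": _sample_ids(n), "group": group}
    for analyte in SCFA_ANALYTES:
        mean = np.full(n, _SCFA_BASELINE[analyte])
        if analyte == "acetate":
            mean[n_per_group:] *= acetate_fold
        data[analyte] = np.exp(
            np.log(mean) - sigma**2 / 2 + rng.normal(0.0, sigma, size=n)
        )
    return pd.DataFrame(data)


def _linear_chain(uptake: float = 10.0, yield_coef: float = 0.5) -> ToyGem:
    model = MetabolicModel(
        id="linear_chain",
        metabolites=(
            Metabolite("A_e", formula="C1", compartment="e"),
            Metabolite("A_c", formula="C1", compartment="c"),
        ),
        reactions=(
            Reaction("EX_A", {"A_e": -1.0}, lower_bound=-uptake),
            Reaction("T_A", {"A_e": -1.0, "A_c": 1.0}),
            Reaction("BIOMASS", {"A_c": -1.0 / yield_coef}),
        ),
        objective="BIOMASS",
    )
    return ToyGem(model, {"optimum": uptake * yield_coef})


def _two_substrate() -> ToyGem:
    # biomass needs 1 A + 2 B; A can be converted to B at a 2:1 loss, so the
    # optimum sits at an interior vertex: max v subject to
    # v + 2*conv <= 10 (A), conv + 6 >= 2v (B) -> v* = 22/5
    model = MetabolicModel(
        id="two_substrate",
        metabolites=(
            Metabolite("A_e", formula="C2", compartment="e"),
            Metabolite("B_e", formula="C3", compartment="e"),
            Metabolite("A", formula="C2", compartment="c"),
            Metabolite("B", formula="C3", compartment="c"),
        ),
        reactions=(
            Reaction("EX_A", {"A_e": -1.0}, lower_bound=-10.0),
            Reaction("EX_B", {"B_e": -1.0}, lower_bound=-6.0),
            Reaction("T_A", {"A_e": -1.0, "A": 1.0}),
            Reaction("T_B", {"B_e": -1.0, "B": 1.0}),
            Reaction("CONV", {"A": -2.0, "B": 1.0}),
            Reaction("BIOMASS", {"A": -1.0, "B": -2.0}),
        ),
        objective="BIOMASS",
    )
    return ToyGem(model, {"optimum": 4.4})


def _cometabolism() -> ToyGem:
    """Acetate enters only through an ACS-like activation to acetyl-CoA and
    the biomass demands a glycolytic precursor (PEP) acetate cannot supply,
    so acetate alone supports no growth; with glycerol, acetate-supplied
    acetyl-CoA spares PEP and raises the optimum.

    Closed forms at carbon cap 100 (glycerol influx u = 100/3):
    glycerol alone u/2, glycerol + acetate 3u/4, acetate alone 0.
    """
    model = MetabolicModel(
        id="cometabolism",
        metabolites=(
            Metabolite("glyc_e", formula="C3H8O3", compartment="e"),
            Metabolite("ac_e", formula="C2H3O2", compartment="e"),
            Metabolite("glyc_c", formula="C3H8O3", compartment="c"),
            Metabolite("ac_c", formula="C2H3O2", compartment="c"),
            Metabolite("pep", formula="C3H2O6P", compartment="c"),
            Metabolite("accoa", formula="C23H34N7O17P3S", compartment="c"),
            Metabolite("atp", formula="C10H12N5O13P3", compartment="c"),
            Metabolite("nadh", formula="C21H27N7O14P2", compartment="c"),
        ),
        reactions=(
            Reaction("EX_glyc", {"glyc_e": -1.0}, lower_bound=0.0),
            Reaction("EX_ac", {"ac_e": -1.0}, lower_bound=0.0),
            Reaction("T_glyc", {"glyc_e": -1.0, "glyc_c": 1.0}),
            Reaction("T_ac", {"ac_e": -1.0, "ac_c": 1.0}),
            Reaction("GLYC_CAT", {"glyc_c": -1.0, "pep": 1.0, "nadh": 1.0}),
            Reaction("PEP_TO_ACCOA", {"pep": -1.0, "accoa": 1.0, "atp": 1.0}),
            Reaction("ACS", {"ac_c": -1.0, "atp": -1.0, "accoa": 1.0}),
            Reaction("NADH_OX", {"nadh": -1.0, "atp": 1.0}),
            Reaction("ATPM", {"atp": -1.0}),
            Reaction("BIOMASS", {"accoa": -1.0, "pep": -1.0, "atp": -1.0}),
        ),
        objective="BIOMASS",
    )
    cap = 100.0
    u = cap / 3.0
    return ToyGem(
        model,
        {
            "carbon_cap": cap,
            "glycerol_alone": u / 2.0,
            "glycerol_plus_acetate": 3.0 * u / 4.0,
            "acetate_alone": 0.0,
        },
    )


_TEMPLATES = {
    "linear_chain": _linear_chain,
    "two_substrate": _two_substrate,
    "cometabolism": _cometabolism,
}


def generate_toy_gem(spec: ToyGemSpec) -> ToyGem:
    """Build a named toy model; optional bound perturbations are applied to
    the model while the stored analytic values describe the unperturbed
    fixture."""
    if spec.template not in _TEMPLATES:
        raise ValueError(
            f"unknown template {spec.template!r}; choose from {sorted(_TEMPLATES)}"
        )
    gem = _TEMPLATES[spec.template]()
    if spec.perturbations:
        gem = ToyGem(gem.model.with_bounds(spec.perturbations), gem.analytic)
    return gem
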