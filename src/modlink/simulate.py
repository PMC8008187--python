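"""Synthetic paired two-tissue longitudinal expression data with planted structure.

The generator emulates a two-diet (HFD vs CD) time-course design: six weeks
(4..24 in steps of 4), four replicate animals per diet x week cell, and for
every animal one islet and one liver RNA-seq sample (paired subjects).

Planted structure, all recorded in a :class:`SyntheticTruth`:

* **Co-expression modules** — per tissue, latent factors ``f_m`` (one value
  per subject) drive member genes through per-gene loadings on the log2
  scale.
* **Cross-tissue coupling** — a coupled (islet module, liver module) pair
  shares a latent ``z``: the islet factor is ``z`` and the liver factor is
  ``rho * z + sqrt(1 - rho^2) * eps``, so ``rho`` is the factor-level
  cross-correlation.
* **Traits** — one endpoint value per subject, a linear function of one
  driving module's factor plus Gaussian noise (or pure noise for null
  traits).
* **Differential expression** — diet-specific log2 shifts on chosen genes
  from a start week onward.

Counts are negative binomial (gamma-Poisson) with a log2 link:

``log2 mean = baseline + factor_scale * loading * f + DE shift + N(0, noise_sd)``

scaled by a per-sample log-normal library depth factor.  A single global
seed feeds one hierarchical ``SeedSequence`` stream per stage, so e.g.
changing the gene count does not perturb trait noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, TraitTable
from .errors import ConfigError

TISSUES = ("islet", "liver")

DEFAULT_WEEKS = (4, 8, 12, 16, 20, 24)
DEFAULT_DIETS = ("HFD", "CD")

# SeedSequence spawn slots, fixed so streams are independent of each other.
_STREAMS = (
    "baselines",
    "loadings",
    "factors",
    "noise",
    "counts",
    "depth",
    "traits",
    "de_selection",
)


@dataclass(frozen=True)
class TraitSpec:
    """One simulated trait: ``value = loading * f_module + N(0, noise_sd)``.

    ``module`` is a planted module index in ``tissue`` or ``None`` for a
    pure-noise (null) trait.
    """

    name: str
    module: int | None
    loading: float
    noise_sd: float
    category: str
    tissue: str = "islet"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic paired-tissue dataset.

    Module sizes are spread evenly across ``module_size_range``; their sum
    plus ``background_gene_count`` must equal ``n_genes_per_tissue``.
    """

    n_genes_per_tissue: int = 2000
    n_modules_per_tissue: int = 8
    module_size_range: tuple[int, int] = (80, 300)
    background_gene_count: int = 480
    loading_range: tuple[float, float] = (0.7, 0.95)
    noise_sd: float = 1.0
    coupling_pairs: tuple[tuple[int, int, float], ...] = ()
    weeks: tuple[int, ...] = DEFAULT_WEEKS
    replicates_per_cell: int = 4
    diets: tuple[str, str] = DEFAULT_DIETS
    de_gene_count: int = 0
    de_log2fc: float = 0.0
    de_start_week: int | None = None
    nb_dispersion: float = 0.1
    trait_specs: tuple[TraitSpec, ...] = ()
    seed: int = 0
    # counts-model knobs
    factor_scale: float = 3.0       # log2 units per unit latent factor
    baseline_log2_range: tuple[float, float] = (3.0, 9.0)
    depth_log_sd: float = 0.15      # sd of per-sample ln depth factor
    # optional hub-gene scheme inside coupled modules (key-gene studies)
    hub_fraction: float = 0.0
    hub_loading_range: tuple[float, float] = (0.95, 1.0)

    # -- derived -------------------------------------------------------
    def module_sizes(self) -> list[int]:
        if self.n_modules_per_tissue == 0:
            return []
        lo, hi = self.module_size_range
        if self.n_modules_per_tissue == 1:
            return [int(lo)]
        return [int(round(s)) for s in
                np.linspace(lo, hi, self.n_modules_per_tissue)]

    @property
    def n_subjects(self) -> int:
        return len(self.weeks) * len(self.diets) * self.replicates_per_cell

    def validate(self) -> None:
        if self.n_genes_per_tissue <= 0:
            raise ConfigError("n_genes_per_tissue must be positive")
        if self.n_modules_per_tissue < 0:
            raise ConfigError("n_modules_per_tissue must be >= 0")
        if self.background_gene_count < 0:
            raise ConfigError("background_gene_count must be >= 0")
        sizes = self.module_sizes()
        if sum(sizes) + self.background_gene_count != self.n_genes_per_tissue:
            raise ConfigError(
                "module sizes sum + background must equal n_genes_per_tissue: "
                f"{sum(sizes)} + {self.background_gene_count} != "
                f"{self.n_genes_per_tissue}"
            )
        lo, hi = self.loading_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigError("loading_range must lie in (0, 1]")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if self.replicates_per_cell <= 0:
            raise ConfigError("replicates_per_cell must be positive")
        if list(self.weeks) != sorted(set(self.weeks)):
            raise ConfigError("weeks must be strictly increasing")
        seen_islet: set[int] = set()
        seen_liver: set[int] = set()
        for im, lm, rho in self.coupling_pairs:
            if not (0.0 <= rho <= 1.0):
                raise ConfigError(f"coupling strength {rho} outside [0, 1]")
            if not (0 <= im < self.n_modules_per_tissue):
                raise ConfigError(f"coupling islet module index {im} out of range")
            if not (0 <= lm < self.n_modules_per_tissue):
                raise ConfigError(f"coupling liver module index {lm} out of range")
            if im in seen_islet or lm in seen_liver:
                raise ConfigError("a module may appear in at most one coupling pair")
            seen_islet.add(im)
            seen_liver.add(lm)
        if not (0.0 <= self.hub_fraction <= 1.0):
            raise ConfigError("hub_fraction must lie in [0, 1]")
        for spec in self.trait_specs:
            if spec.module is not None and not (
                0 <= spec.module < self.n_modules_per_tissue
            ):
                raise ConfigError(
                    f"trait {spec.name!r} driving module index out of range"
                )
            if spec.tissue not in TISSUES:
                raise ConfigError(f"trait {spec.name!r} has unknown tissue")


@dataclass
class SyntheticTruth:
    """Ground-truth record of everything the generator planted."""

    partition_per_tissue: dict[str, pd.Series]       # gene -> module label
    factor_matrix_per_tissue: dict[str, pd.DataFrame]  # module x subject
    coupling_matrix: pd.DataFrame                    # islet module x liver module
    trait_loadings: dict[str, tuple[str, int | None, float]]  # trait -> (tissue, module, coef)
    de_genes_per_week: dict[int, set[tuple[str, str, float]]]  # week -> {(gene, tissue, lfc)}
    loadings_per_tissue: dict[str, pd.Series] = field(default_factory=dict)

    def module_genes(self, tissue: str, module_idx: int) -> list[str]:
        label = f"M{module_idx + 1}"
        part = self.partition_per_tissue[tissue]
        return list(part.index[part == label])

    def de_union(self, tissue: str) -> set[str]:
        out: set[str] = set()
        for entries in self.de_genes_per_week.values():
            out |= {g for g, t, _ in entries if t == tissue}
        return out


# ---------------------------------------------------------------------------


def _subject_frame(config: SimConfig) -> pd.DataFrame:
    rows = []
    for week in config.weeks:
        for diet in config.diets:
            for rep in range(1, config.replicates_per_cell + 1):
                rows.append(
                    {
                        "subject_id": f"{diet}_w{week:02d}_r{rep}",
                        "week": week,
                        "diet": diet,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def _gene_ids(tissue: str, n: int) -> list[str]:
    prefix = "isl" if tissue == "islet" else "liv"
    return [f"{prefix}_g{i + 1:05d}" for i in range(n)]


def _partition_labels(config: SimConfig) -> list[str]:
    labels: list[str] = []
    for m, size in enumerate(config.module_sizes()):
        labels.extend([f"M{m + 1}"] * size)
    labels.extend(["unassigned"] * config.background_gene_count)
    return labels


def _draw_factors(config: SimConfig, rng: np.random.Generator,
                  n_subjects: int) -> dict[str, np.ndarray]:
    """Latent factors per tissue (module x subject), with coupling."""
    k = config.n_modules_per_tissue
    factors = {
        "islet": rng.standard_normal((k, n_subjects)) if k else np.empty((0, n_subjects)),
        "liver": rng.standard_normal((k, n_subjects)) if k else np.empty((0, n_subjects)),
    }
    for im, lm, rho in config.coupling_pairs:
        z = rng.standard_normal(n_subjects)
        eps = rng.standard_normal(n_subjects)
        factors["islet"][im] = z
        factors["liver"][lm] = rho * z + np.sqrt(1.0 - rho**2) * eps
    return factors


def _draw_loadings(config: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-gene loadings; coupled modules may carry a hub subpopulation."""
    sizes = config.module_sizes()
    coupled = {
        "islet": {im for im, _, _ in config.coupling_pairs},
        "liver": {lm for _, lm, _ in config.coupling_pairs},
    }
    lo, hi = config.loading_range
    hlo, hhi = config.hub_loading_range
    out: dict[str, np.ndarray] = {}
    for tissue in TISSUES:
        loads = np.zeros(config.n_genes_per_tissue)
        pos = 0
        for m, size in enumerate(sizes):
            vals = rng.uniform(lo, hi, size)
            if config.hub_fraction > 0 and m in coupled[tissue]:
                n_hub = int(round(config.hub_fraction * size))
                hub_idx = rng.choice(size, size=n_hub, replace=False)
                vals[hub_idx] = rng.uniform(hlo, hhi, n_hub)
            loads[pos:pos + size] = vals
            pos += size
        out[tissue] = loads
    return out


def _select_de_genes(config: SimConfig, rng: np.random.Generator,
                     labels: list[str]) -> dict[str, list[tuple[int, float]]]:
    """Choose DE genes per tissue (background genes first) with signed shifts."""
    out: dict[str, list[tuple[int, float]]] = {t: [] for t in TISSUES}
    if config.de_gene_count == 0 or config.de_log2fc == 0.0:
        return out
    background = [i for i, lab in enumerate(labels) if lab == "unassigned"]
    pool = background if len(background) >= config.de_gene_count else list(
        range(config.n_genes_per_tissue)
    )
    for tissue in TISSUES:
        chosen = rng.choice(len(pool), size=config.de_gene_count, replace=False)
        signs = rng.choice([-1.0, 1.0], size=config.de_gene_count)
        out[tissue] = [
            (pool[int(c)], float(s) * config.de_log2fc)
            for c, s in zip(chosen, signs)
        ]
    return out


def generate_dataset(
    config: SimConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, TraitTable, SyntheticTruth]:
    """Generate paired islet and liver count matrices, traits, and the truth.

    Deterministic: identical config (including seed) gives bit-identical
    output.
    """
    config.validate()
    streams = dict(
        zip(_STREAMS, np.random.SeedSequence(config.seed).spawn(len(_STREAMS)))
    )
    rngs = {name: np.random.default_rng(ss) for name, ss in streams.items()}

    subjects = _subject_frame(config)
    n_sub = len(subjects)
    labels = _partition_labels(config)
    module_of_gene = np.array(
        [int(lab[1:]) - 1 if lab != "unassigned" else -1 for lab in labels]
    )

    factors = _draw_factors(config, rngs["factors"], n_sub)
    loadings = _draw_loadings(config, rngs["loadings"])
    de_choice = _select_de_genes(config, rngs["de_selection"], labels)
    de_start = config.de_start_week if config.de_start_week is not None else (
        config.weeks[0] if config.weeks else 0
    )

    hfd = config.diets[0]
    matrices: dict[str, ExpressionMatrix] = {}
    truth_partitions: dict[str, pd.Series] = {}
    truth_factors: dict[str, pd.DataFrame] = {}
    truth_loadings: dict[str, pd.Series] = {}
    de_per_week: dict[int, set[tuple[str, str, float]]] = {
        w: set() for w in config.weeks
    }

    for tissue in TISSUES:
        genes = _gene_ids(tissue, config.n_genes_per_tissue)
        baselines = rngs["baselines"].uniform(
            *config.baseline_log2_range, config.n_genes_per_tissue
        )
        # signal on the log2 scale: baseline + factor_scale * loading * factor
        lam = np.tile(baselines[:, None], (1, n_sub))
        in_module = module_of_gene >= 0
        if in_module.any():
            lam[in_module] += (
                config.factor_scale
                * loadings[tissue][in_module, None]
                * factors[tissue][module_of_gene[in_module]]
            )
        # diet-specific DE shifts from de_start onward
        de_mask = (
            (subjects["diet"] == hfd) & (subjects["week"] >= de_start)
        ).to_numpy()
        for gi, shift in de_choice[tissue]:
            lam[gi, de_mask] += shift
            for w in config.weeks:
                if w >= de_start:
                    de_per_week[w].add((genes[gi], tissue, shift))
        lam += rngs["noise"].normal(
            0.0, config.noise_sd, size=(config.n_genes_per_tissue, n_sub)
        )
        depth = np.exp(
            rngs["depth"].normal(0.0, config.depth_log_sd, size=n_sub)
        )
        mu = np.exp2(lam) * depth[None, :]
        shape = 1.0 / config.nb_dispersion
        lam_pois = rngs["counts"].gamma(
            shape, mu * config.nb_dispersion, size=mu.shape
        )
        counts = rngs["counts"].poisson(lam_pois)

        sample_ids = [f"{tissue}_{s}" for s in subjects["subject_id"]]
        values = pd.DataFrame(
            counts, index=pd.Index(genes, name="gene_id"), columns=sample_ids
        )
        meta = subjects.copy()
        meta["tissue"] = tissue
        meta["sample_id"] = sample_ids
        meta = meta.set_index("sample_id")[
            ["subject_id", "tissue", "week", "diet", "replicate"]
        ]
        matrices[tissue] = ExpressionMatrix(values, meta, scale="counts")
        truth_partitions[tissue] = pd.Series(labels, index=genes, name="module")
        truth_factors[tissue] = pd.DataFrame(
            factors[tissue],
            index=[f"M{m + 1}" for m in range(config.n_modules_per_tissue)],
            columns=list(subjects["subject_id"]),
        )
        truth_loadings[tissue] = pd.Series(
            loadings[tissue], index=genes, name="loading"
        )

    # traits: one value per subject from the driving module's factor
    trait_cols: dict[str, np.ndarray] = {}
    trait_cats: dict[str, str] = {}
    trait_load: dict[str, tuple[str, int | None, float]] = {}
    for spec in config.trait_specs:
        noise = rngs["traits"].normal(0.0, spec.noise_sd, size=n_sub)
        if spec.module is None:
            vals = noise
        else:
            vals = spec.loading * factors[spec.tissue][spec.module] + noise
        trait_cols[spec.name] = vals
        trait_cats[spec.name] = spec.category
        trait_load[spec.name] = (spec.tissue, spec.module, spec.loading)
    subject_index = pd.Index(list(subjects["subject_id"]), name="subject_id")
    if trait_cols:
        trait_values = pd.DataFrame(trait_cols, index=subject_index)
    else:
        # keep a minimal weight-like null trait so the table is never empty
        trait_values = pd.DataFrame(
            {"weight": rngs["traits"].normal(30.0, 3.0, size=n_sub)},
            index=subject_index,
        )
        trait_cats = {"weight": "general"}
        trait_load = {"weight": ("islet", None, 0.0)}
    traits = TraitTable(trait_values, pd.Series(trait_cats))

    coupling = pd.DataFrame(
        0.0,
        index=[f"M{m + 1}" for m in range(config.n_modules_per_tissue)],
        columns=[f"M{m + 1}" for m in range(config.n_modules_per_tissue)],
    )
    for im, lm, rho in config.coupling_pairs:
        coupling.iloc[im, lm] = rho

    truth = SyntheticTruth(
        partition_per_tissue=truth_partitions,
        factor_matrix_per_tissue=truth_factors,
        coupling_matrix=coupling,
        trait_loadings=trait_load,
        de_genes_per_week=de_per_week,
        loadings_per_tissue=truth_loadings,
    )
    return matrices["islet"], matrices["liver"], traits, truth


def null_dataset(
    config: SimConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, TraitTable, SyntheticTruth]:
    """As :func:`generate_dataset` but with no planted structure at all.

    Zero modules, zero coupling, zero DE effect; genes are i.i.d. negative
    binomial.  Traits driven by modules become pure noise.
    """
    config.validate()
    null_traits = tuple(
        replace(spec, module=None) for spec in config.trait_specs
    )
    null_config = replace(
        config,
        n_modules_per_tissue=0,
        module_size_range=(0, 0),
        background_gene_count=config.n_genes_per_tissue,
        coupling_pairs=(),
        de_gene_count=0,
        de_log2fc=0.0,
        trait_specs=null_traits,
    )
    return generate_dataset(null_config)


# -- presets ----------------------------------------------------------------


def _standard_trait_specs() -> tuple[TraitSpec, ...]:
    """Trait panel emulating the study's endpoint measurements.

    Six insulin-secretion parameters (IPGTT-derived) driven by the first
    three islet modules, two liver-enzyme traits driven by liver modules,
    and null metabolic traits.
    """
    return (
        TraitSpec("auc_insulin", 0, 0.8, 0.5, "insulin_secretion", "islet"),
        TraitSpec("fasting_insulin", 0, 0.8, 0.5, "insulin_secretion", "islet"),
        TraitSpec("first_phase_ratio", 1, 0.8, 0.5, "insulin_secretion", "islet"),
        TraitSpec("peak_insulin", 1, 0.8, 0.5, "insulin_secretion", "islet"),
        TraitSpec("insulinogenic_index", 2, 0.8, 0.5, "insulin_secretion", "islet"),
        TraitSpec("basal_secretion", 2, 0.8, 0.5, "insulin_secretion", "islet"),
        TraitSpec("alt", 0, 0.8, 0.5, "liver_enzyme", "liver"),
        TraitSpec("ast", 1, 0.8, 0.5, "liver_enzyme", "liver"),
        TraitSpec("weight", None, 0.0, 1.0, "general", "islet"),
        TraitSpec("energy_intake", None, 0.0, 1.0, "general", "islet"),
        TraitSpec("fasting_glucose", None, 0.0, 1.0, "glycemia", "islet"),
        TraitSpec("tg", None, 0.0, 1.0, "lipid", "liver"),
    )


def planted_modules_config(seed: int = 1) -> SimConfig:
    """Module- and coupling-recovery conditions: 2,000 genes per tissue,
    8 modules of 80-300 genes, loadings U(0.7, 0.95), noise sd 1, three
    coupled module pairs at rho = 0.9, 48 paired samples."""
    return SimConfig(
        n_genes_per_tissue=2000,
        n_modules_per_tissue=8,
        module_size_range=(80, 300),
        background_gene_count=480,
        loading_range=(0.7, 0.95),
        noise_sd=1.0,
        coupling_pairs=((0, 0, 0.9), (1, 1, 0.9), (2, 2, 0.9)),
        nb_dispersion=0.1,
        trait_specs=_standard_trait_specs(),
        seed=seed,
    )


def key_gene_config(seed: int = 1) -> SimConfig:
    """Key-gene recovery conditions: coupled modules carry a 20% hub
    subpopulation with loadings in [0.95, 1.0] against a [0.35, 0.55]
    body, so module membership above 0.9 is informative about hubs."""
    return replace(
        planted_modules_config(seed),
        loading_range=(0.35, 0.55),
        hub_fraction=0.2,
        hub_loading_range=(0.95, 1.0),
    )


def de_calibration_config(seed: int = 1) -> SimConfig:
    """Differential-expression power conditions: 2,000 genes, no modules,
    100 DE genes at |log2fc| = 3, low dispersion, 4 vs 4 per week.

    Noise is dominated by the negative-binomial counts (dispersion 0.05);
    the extra log-normal spread is kept small so "low dispersion" is the
    operative condition.
    """
    return SimConfig(
        n_genes_per_tissue=2000,
        n_modules_per_tissue=0,
        module_size_range=(0, 0),
        background_gene_count=2000,
        noise_sd=0.2,
        de_gene_count=100,
        de_log2fc=3.0,
        nb_dispersion=0.05,
        trait_specs=_standard_trait_specs()[-4:],
        seed=seed,
    )


def demo_config(seed: int = 1) -> SimConfig:
    """Small end-to-end configuration for demos and pipeline tests."""
    return SimConfig(
        n_genes_per_tissue=600,
        n_modules_per_tissue=4,
        module_size_range=(60, 120),
        background_gene_count=240,
        loading_range=(0.7, 0.95),
        noise_sd=0.5,
        coupling_pairs=((0, 0, 0.9),),
        de_gene_count=40,
        de_log2fc=3.0,
        nb_dispersion=0.05,
        trait_specs=_standard_trait_specs(),
        seed=seed,
    )


# -- writers ----------------------------------------------------------------


def write_dataset(
    outdir: str | Path,
    islet: ExpressionMatrix,
    liver: ExpressionMatrix,
    traits: TraitTable,
    truth: SyntheticTruth | None = None,
) -> list[Path]:
    """Write the standard pipeline input files; returns the paths written.

    Counts: TSV per tissue (genes in rows).  Sample metadata: one CSV for
    both tissues.  Traits and trait categories: CSV.  Truth: TSV partition
    per tissue plus one JSON with coupling, trait loadings, and DE sets.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for name, em in (("islet", islet), ("liver", liver)):
        p = outdir / f"counts_{name}.tsv"
        em.values.to_csv(p, sep="\t", index_label="gene_id")
        written.append(p)

    meta = pd.concat([islet.meta(), liver.meta()])
    p = outdir / "samples.csv"
    meta.to_csv(p, index_label="sample_id")
    written.append(p)

    p = outdir / "traits.csv"
    traits.values.to_csv(p, index_label="subject_id")
    written.append(p)
    p = outdir / "trait_categories.csv"
    traits.categories.rename("category").to_csv(p, index_label="trait")
    written.append(p)

    if truth is not None:
        for tissue, part in truth.partition_per_tissue.items():
            p = outdir / f"truth_partition_{tissue}.tsv"
            frame = part.to_frame()
            frame["loading"] = truth.loadings_per_tissue.get(
                tissue, pd.Series(dtype=float)
            )
            frame.to_csv(p, sep="\t", index_label="gene_id")
            written.append(p)
        payload = {
            "coupling_matrix": truth.coupling_matrix.to_dict(),
            "trait_loadings": {
                k: list(v) for k, v in truth.trait_loadings.items()
            },
            "de_genes_per_week": {
                str(w): sorted([g, t, fc] for g, t, fc in entries)
                for w, entries in truth.de_genes_per_week.items()
            },
        }
        p = outdir / "truth.json"
        p.write_text(json.dumps(payload, indent=1, sort_keys=True))
        written.append(p)
    return written
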