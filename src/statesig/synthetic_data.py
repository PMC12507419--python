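"""Synthetic multi-category RNA-seq count matrices with known ground truth.

The generator emulates a merged reference of public bulk RNA-seq datasets:
several physiological-state categories, each observed in multiple
independent datasets with a few replicates, negative-binomial counts with
a shared dispersion, additive log-scale batch offsets, and per-sample
library-size factors. A subset of genes per category is "informative":
shifted up or down on the log2 scale by a stated multiple of the
approximate within-group SD of log2 expression, so that selector
precision/recall and classifier accuracy can be scored against planted
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

_LN2 = np.log(2.0)


@dataclass
class SyntheticSpec:
    """Parameters of one simulated study.

    ``effect_size`` is the planted log2 mean shift in units of the
    (approximate) within-group SD of log2 expression for each informative
    gene, so an effect of 2 means category means separated by two
    within-group SDs. ``baseline_log2_mean_range`` bounds the per-gene
    baseline log2 mean count; ``libsize_log2_range`` bounds the log2 of
    per-sample library-size factors (drawn log-uniformly).
    """

    n_categories: int = 3
    datasets_per_category: int = 9
    replicates_per_dataset: int = 3
    n_genes: int = 5000
    n_informative_per_category: int = 100
    effect_size: float = 2.0
    nb_dispersion: float = 0.05
    baseline_log2_mean_range: tuple = (3.0, 10.0)
    batch_effect_sd: float = 0.5
    n_batches: int = 3
    libsize_log2_range: tuple = (-0.5, 0.5)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_categories", "datasets_per_category",
                     "replicates_per_dataset", "n_genes",
                     "n_informative_per_category", "n_batches"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.effect_size < 0:
            raise ValueError(f"effect_size must be >= 0, got {self.effect_size}")
        if self.nb_dispersion <= 0:
            raise ValueError(
                f"nb_dispersion must be > 0, got {self.nb_dispersion}"
            )
        if self.batch_effect_sd < 0:
            raise ValueError(
                f"batch_effect_sd must be >= 0, got {self.batch_effect_sd}"
            )
        if self.n_categories * self.n_informative_per_category > self.n_genes:
            raise ValueError("more informative genes requested than genes exist")
        lo, hi = self.baseline_log2_mean_range
        if not lo < hi:
            raise ValueError("baseline_log2_mean_range must be increasing")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a simulated matrix.

    ``informative`` maps category -> DataFrame(gene, direction, log2_fc);
    the per-category sets are disjoint. ``assignments`` carries the
    per-sample category/dataset/batch bookkeeping (same content as the
    returned metadata).
    """

    informative: dict
    assignments: pd.DataFrame
    spec: SyntheticSpec = field(repr=False, default=None)

    def informative_genes(self) -> list:
        out = []
        for cat in self.informative:
            out.extend(self.informative[cat]["gene"].tolist())
        return out


def _nb_sd_log2(mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Delta-method SD of log2(count + 1) for NB(mu, dispersion)."""
    return np.sqrt(1.0 / mu + dispersion) / _LN2


def simulate_counts(spec: SyntheticSpec):
    """Draw a count matrix, metadata table and planted truth.

    Counts are NB with mean 2**(base + effect + batch + libsize) and
    dispersion ``nb_dispersion`` (variance mu + dispersion * mu^2).
    Identical seeds give bitwise-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = np.array([f"g{i:05d}" for i in range(spec.n_genes)])
    categories = [f"cat{c}" for c in range(spec.n_categories)]

    base_log2 = rng.uniform(*spec.baseline_log2_mean_range, size=spec.n_genes)
    sd_log2 = _nb_sd_log2(2.0 ** base_log2, spec.nb_dispersion)

    # disjoint informative sets, one per category, with random +/- direction
    pool = rng.permutation(spec.n_genes)
    informative = {}
    lfc = np.zeros((spec.n_genes, spec.n_categories))
    for c, cat in enumerate(categories):
        start = c * spec.n_informative_per_category
        idx = np.sort(pool[start:start + spec.n_informative_per_category])
        direction = rng.choice([-1.0, 1.0], size=len(idx))
        shifts = spec.effect_size * sd_log2[idx] * direction
        lfc[idx, c] = shifts
        informative[cat] = pd.DataFrame({
            "gene": genes[idx],
            "direction": direction.astype(int),
            "log2_fc": shifts,
        })

    # datasets interleaved across categories; batch cycles over datasets so
    # every batch spans all categories (batch never aliases category)
    sample_rows = []
    for c, cat in enumerate(categories):
        for d in range(spec.datasets_per_category):
            dataset = f"{cat}_ds{d}"
            batch = f"batch{d % spec.n_batches}"
            for r in range(spec.replicates_per_dataset):
                sample_rows.append({
                    "sample": f"{dataset}_r{r}",
                    "category": cat,
                    "dataset": dataset,
                    "batch": batch,
                    "is_control": False,
                })
    meta = pd.DataFrame(sample_rows).set_index("sample")
    n_samples = len(meta)

    batch_names = sorted(meta["batch"].unique())
    batch_offsets = {
        b: rng.normal(0.0, spec.batch_effect_sd, size=spec.n_genes)
        for b in batch_names
    }
    libsize_log2 = rng.uniform(*spec.libsize_log2_range, size=n_samples)

    cat_index = np.array([categories.index(c) for c in meta["category"]])
    log2_mu = (
        base_log2[:, None]
        + lfc[:, cat_index]
        + np.column_stack([batch_offsets[b] for b in meta["batch"]])
        + libsize_log2[None, :]
    )
    mu = 2.0 ** log2_mu
    r_param = 1.0 / spec.nb_dispersion
    p_param = r_param / (r_param + mu)
    counts = rng.negative_binomial(r_param, p_param)
    counts_df = pd.DataFrame(counts, index=genes, columns=meta.index)
    truth = SyntheticTruth(informative=informative, assignments=meta.copy(),
                           spec=spec)
    return counts_df, meta, truth


def default_scenario(seed: int = 1234) -> SyntheticSpec:
    """The reference study conditions used throughout the test suite.

    Three categories x nine datasets x three replicates (81 samples, 27
    datasets — the shape of a merged multi-lab reference), 5000 genes with
    100 informative genes per category at effect size 2 within-group SDs,
    three batches.
    """
    return SyntheticSpec(
        n_categories=3,
        datasets_per_category=9,
        replicates_per_dataset=3,
        n_genes=5000,
        n_informative_per_category=100,
        effect_size=2.0,
        nb_dispersion=0.05,
        batch_effect_sd=0.5,
        n_batches=3,
        seed=seed,
    )


def small_scenario(seed: int = 1234, effect_size: float = 1.0) -> SyntheticSpec:
    """A scaled-down noisy scenario for repeat-heavy protocols.

    Three categories x nine datasets x two replicates, 2000 genes, 60
    informative genes per category, default effect size 1 within-group SD:
    deliberately noisy so accuracy degrades visibly as the reference is
    subsampled, while nine datasets per category keep at least two units
    per category even at a 20% stratified subsample.
    """
    return SyntheticSpec(
        n_categories=3,
        datasets_per_category=9,
        replicates_per_dataset=2,
        n_genes=2000,
        n_informative_per_category=60,
        effect_size=effect_size,
        nb_dispersion=0.05,
        batch_effect_sd=0.5,
        n_batches=3,
        seed=seed,
    )
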