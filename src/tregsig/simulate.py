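"""Synthetic 18-library experiments with planted gene classes and a truth table.

The generator emulates the study design the analysis expects: three thymic
donors contributing sorted thymic Treg/Tconv libraries and three blood
donors contributing naive and memory Treg/Tconv libraries (18 libraries in
total).  Counts are negative-binomial with variance ``mu + phi * mu**2``;
gene means are ``2**(baseline + planted class effect + donor effect)``
converted to expected counts at the drawn library depth.  Every planted
class (up/down DEG, "private" gene, trajectory cell) is recorded in a truth
table that downstream recovery tests compare against.

Planted expression values are stated in log2-CPM units.  Because CPM is a
relative measure, the generator calibrates the null-gene baselines with a
single scalar shift so that the geometric-mean nominal per-sample total is
exactly 1e6; planted values (reference gene, DEG and private baselines) are
never shifted, so configured log2-CPM levels are realized on the observed
scale once TMM normalization has removed per-sample composition offsets.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneSet, GeneSetCollection

SIGNATURE_NULL = "null"
SIGNATURE_UP = "up_deg"
SIGNATURE_DOWN = "down_deg"

TRAJECTORY_CELLS = tuple(
    f"{c1}_{c2}" for c1 in ("down", "stable", "up") for c2 in ("down", "stable", "up")
)
NOT_APPLICABLE = "not_applicable"

#: default allocation of private genes over the nine (C1, C2) trajectory
#: cells, mirroring the relative cell sizes of the study design
DEFAULT_TRAJECTORY_FRACTIONS: dict[str, float] = {
    "down_stable": 0.54,
    "down_up": 0.20,
    "up_stable": 0.09,
    "stable_up": 0.04,
    "stable_stable": 0.09,
    "down_down": 0.01,
    "up_up": 0.01,
    "up_down": 0.02,
    "stable_down": 0.00,
}


@dataclasses.dataclass
class SimulationParams:
    """Knobs of the synthetic experiment.

    ``dispersion`` is the NB dispersion phi (variance ``mu + phi mu^2``);
    ``donor_sd`` the SD of the per-donor, per-gene log2 shift shared across
    populations of that donor; ``planted_lfc`` the magnitude (log2) of every
    planted class effect; ``reference_gene_tconv_log2_mean`` the log2-CPM of
    the reference gene in conventional-lineage samples, which downstream
    analysis re-estimates as the private-gene threshold.  Fractions are of
    all genes; private genes are up-DEGs over and above ``frac_up_deg``.
    """

    n_genes: int = 15_000
    baseline_log2_mean_range: tuple[float, float] = (2.0, 10.0)
    dispersion: float = 0.1
    donor_sd: float = 0.15
    lib_size_mean: int = 20_000_000
    lib_size_cv: float = 0.15
    frac_up_deg: float = 0.045
    frac_down_deg: float = 0.04
    frac_private: float = 0.02
    planted_lfc: float = 2.0
    reference_gene_tconv_log2_mean: float = 4.0
    reference_gene_treg_elevation: float = 4.0
    trajectory_class_fractions: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_TRAJECTORY_FRACTIONS)
    )
    downup_thymus_fraction: float = 33.0 / 48.0
    reference_gene: str = "IL2RA"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.planted_lfc <= 0:
            raise ValueError("planted_lfc must be > 0")
        fracs = (self.frac_up_deg, self.frac_down_deg, self.frac_private)
        if any(f < 0 for f in fracs):
            raise ValueError("class fractions must be >= 0")
        if sum(fracs) > 1.0 + 1e-12:
            raise ValueError("class fractions must sum to at most 1")
        tf = self.trajectory_class_fractions
        unknown = set(tf) - set(TRAJECTORY_CELLS)
        if unknown:
            raise ValueError(f"unknown trajectory cell(s): {sorted(unknown)}")
        if any(v < 0 for v in tf.values()) or sum(tf.values()) > 1.0 + 1e-9:
            raise ValueError("trajectory fractions must be >= 0 and sum to at most 1")
        lo, hi = self.baseline_log2_mean_range
        if not lo < hi:
            raise ValueError("baseline_log2_mean_range must be an increasing interval")
        n_planted = (
            round(self.n_genes * self.frac_up_deg)
            + round(self.n_genes * self.frac_down_deg)
            + round(self.n_genes * self.frac_private)
            + 1  # reference gene
        )
        if n_planted > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small to allocate all planted classes"
            )


POPULATIONS = (
    ("thymus", "Treg"),
    ("thymus", "Tconv"),
    ("naive", "Treg"),
    ("naive", "Tconv"),
    ("memory", "Treg"),
    ("memory", "Tconv"),
)


def _sample_table() -> pd.DataFrame:
    rows = []
    for donor in ("TD1", "TD2", "TD3"):
        for comp, lin in POPULATIONS[:2]:
            rows.append((f"{comp[0]}{lin}_{donor}", donor, comp, lin))
    for donor in ("BD1", "BD2", "BD3"):
        for comp, lin in POPULATIONS[2:]:
            rows.append((f"{comp[0]}{lin}_{donor}", donor, comp, lin))
    meta = pd.DataFrame(rows, columns=["sample_id", "donor_id", "compartment", "lineage"])
    return meta.set_index("sample_id")


def _allocate_counts(n: int, fractions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of ``n`` items over the given fractions."""
    items = list(fractions.items())
    raw = [n * f for _, f in items]
    base = [int(np.floor(r)) for r in raw]
    rem = n - sum(base) if abs(sum(fractions.values()) - 1.0) < 1e-9 else 0
    order = np.argsort([-(r - b) for r, b in zip(raw, base)], kind="stable")
    for i in range(rem):
        base[order[i]] += 1
    return {k: b for (k, _), b in zip(items, base)}


def _calibrate_null_shift(null_mass: np.ndarray, planted_mass: np.ndarray) -> float:
    """Scalar c so geomean_s(null_mass_s * 2**-c + planted_mass_s) == 1e6."""
    target = np.log(1e6)

    def excess(c: float) -> float:
        return float(np.mean(np.log(null_mass * 2.0**-c + planted_mass)) - target)

    lo, hi = -40.0, 40.0
    if excess(hi) > 0:
        raise ValueError(
            "planted genes alone exceed the 1e6 CPM budget; lower planted levels"
        )
    if excess(lo) < 0:
        raise ValueError("total expression mass below the 1e6 CPM budget")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if excess(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_experiment(params: SimulationParams) -> tuple[CountMatrix, pd.DataFrame]:
    """Generate counts for the 18-library design plus the per-gene truth table.

    The truth table is indexed by gene id with columns ``signature_class``
    (null/up_deg/down_deg for the thymic Treg-vs-Tconv contrast),
    ``is_private``, ``trajectory_class`` (one of the nine C1/C2 cells or
    ``not_applicable``), ``thymus_enriched`` and the planted per-population
    log2-CPM means.  Identical parameters and seed give bit-identical
    output.
    """
    rng = np.random.default_rng(params.seed)
    meta = _sample_table()
    n = params.n_genes
    lfc = params.planted_lfc
    ref_tconv = params.reference_gene_tconv_log2_mean
    lo, hi = params.baseline_log2_mean_range

    n_private = round(n * params.frac_private)
    n_up = round(n * params.frac_up_deg)
    n_down = round(n * params.frac_down_deg)

    gene_ids = np.array(
        [params.reference_gene] + [f"G{i:05d}" for i in range(1, n)], dtype=object
    )
    # class assignment: a random permutation of the non-reference genes
    perm = 1 + rng.permutation(n - 1)
    idx_private = perm[:n_private]
    idx_up = perm[n_private : n_private + n_up]
    idx_down = perm[n_private + n_up : n_private + n_up + n_down]

    signature_class = np.full(n, SIGNATURE_NULL, dtype=object)
    if params.reference_gene_treg_elevation > 0:
        signature_class[0] = SIGNATURE_UP
    signature_class[idx_private] = SIGNATURE_UP
    signature_class[idx_up] = SIGNATURE_UP
    signature_class[idx_down] = SIGNATURE_DOWN
    is_private = np.zeros(n, dtype=bool)
    is_private[idx_private] = True

    # baselines (log2-CPM of the conventional lineage / unaffected state);
    # planted classes are placed above the 1-CPM detection floor and, for up
    # vs private genes, on opposite sides of the reference threshold so the
    # planted private rule is well defined (see docs/methods.md)
    baseline = rng.uniform(lo, hi, size=n)
    baseline[idx_up] = rng.uniform(min(ref_tconv + 1.0, hi - 0.5), hi, size=n_up)
    baseline[idx_down] = rng.uniform(min(lo + lfc + 0.5, hi - 0.5), hi, size=n_down)
    baseline[idx_private] = rng.uniform(ref_tconv - 2.0, ref_tconv - 1.0, size=n_private)
    baseline[0] = ref_tconv

    # trajectory cells for private genes
    cell_counts = _allocate_counts(n_private, dict(params.trajectory_class_fractions))
    trajectory_class = np.full(n, NOT_APPLICABLE, dtype=object)
    cells_in_order: list[str] = []
    for cell in TRAJECTORY_CELLS:
        cells_in_order.extend([cell] * cell_counts.get(cell, 0))
    cells_in_order.extend(["stable_stable"] * (n_private - len(cells_in_order)))
    trajectory_class[idx_private] = np.array(cells_in_order, dtype=object)

    # planted per-population log2 means (genes x 6 populations)
    pop = np.tile(baseline[:, None], (1, 6))
    col = {f"{c}.{l}": j for j, (c, l) in enumerate(POPULATIONS)}
    t_treg, n_treg, m_treg = col["thymus.Treg"], col["naive.Treg"], col["memory.Treg"]

    pop[idx_up, t_treg] += lfc
    pop[idx_down, t_treg] -= lfc
    # non-private DEG effects persist across the Treg compartments
    pop[idx_up, n_treg] += lfc
    pop[idx_up, m_treg] += lfc
    pop[idx_down, n_treg] -= lfc
    pop[idx_down, m_treg] -= lfc

    step = {"down": -1.0, "stable": 0.0, "up": 1.0}
    thymus_gt_memory = np.zeros(n, dtype=bool)
    downup = [g for g in idx_private if trajectory_class[g] == "down_up"]
    n_thy_greater = round(len(downup) * params.downup_thymus_fraction)
    downup_thy = set(downup[:n_thy_greater])
    for g in idx_private:
        c1, c2 = trajectory_class[g].split("_")
        s1 = step[c1] * lfc
        s2 = step[c2] * lfc
        if trajectory_class[g] == "down_up":
            # asymmetric steps: symmetric ones would land memory exactly on
            # the thymic level and make the tiebreak a coin flip
            if g in downup_thy:
                s1 = -1.5 * lfc
                thymus_gt_memory[g] = True
            else:
                s2 = 1.5 * lfc
        thy = baseline[g] + lfc
        pop[g, t_treg] = thy
        pop[g, n_treg] = thy + s1
        pop[g, m_treg] = thy + s1 + s2

    pop[0, [t_treg, n_treg, m_treg]] = ref_tconv + params.reference_gene_treg_elevation

    thymus_enriched = is_private & (
        np.isin(trajectory_class, ("down_stable", "down_down"))
        | ((trajectory_class == "down_up") & thymus_gt_memory)
    )

    # donor effects: one log2 shift per donor per gene, shared across that
    # donor's populations
    donors = list(dict.fromkeys(meta["donor_id"]))
    donor_eff = rng.normal(0.0, params.donor_sd, size=(n, len(donors)))
    donor_col = {d: j for j, d in enumerate(donors)}

    # library sizes around lib_size_mean with the configured CV (log-normal)
    sigma2 = np.log1p(params.lib_size_cv**2)
    mu_log = np.log(params.lib_size_mean) - sigma2 / 2.0
    lib_draw = np.maximum(
        1, np.round(rng.lognormal(mu_log, np.sqrt(sigma2), size=len(meta)))
    ).astype(np.int64)

    # per-sample nominal log2-CPM, then null-mass calibration to the 1e6 budget
    sample_log2 = np.empty((n, len(meta)))
    for k, (sid, row) in enumerate(meta.iterrows()):
        j = col[f"{row['compartment']}.{row['lineage']}"]
        sample_log2[:, k] = pop[:, j] + donor_eff[:, donor_col[row["donor_id"]]]
    # the reference gene is never shifted: its configured absolute level is
    # the private-rule threshold downstream analysis must be able to recover
    planted_mask = (signature_class != SIGNATURE_NULL) | is_private
    planted_mask[0] = True
    # calibrate on the thymic libraries: the reference threshold is an
    # absolute log2-CPM level measured in the thymic analysis, whose TMM
    # normalization centres every library on the thymic geometric-mean
    # total; every other stage only uses scale-invariant comparisons
    thymic_cols = np.flatnonzero((meta["compartment"] == "thymus").to_numpy())
    mass = 2.0 ** sample_log2[:, thymic_cols]
    shift = _calibrate_null_shift(
        mass[~planted_mask].sum(axis=0), mass[planted_mask].sum(axis=0)
    )
    sample_log2[~planted_mask] -= shift

    # NB sampling via gamma-Poisson; one column at a time, fixed order
    phi = params.dispersion
    counts = np.empty((n, len(meta)), dtype=np.int64)
    expected_totals = np.empty(len(meta))
    for k in range(len(meta)):
        mu = 2.0 ** sample_log2[:, k] * (lib_draw[k] / 1e6)
        lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
        counts[:, k] = rng.poisson(lam)
        expected_totals[k] = mu.sum()

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=meta.index)
    cm = CountMatrix(counts=counts_df, samples=meta.copy())
    cm.counts.attrs["lib_size_targets"] = dict(zip(meta.index, expected_totals))

    truth = pd.DataFrame(
        {
            "signature_class": signature_class,
            "is_private": is_private,
            "trajectory_class": trajectory_class,
            "thymus_enriched": thymus_enriched,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    for name, j in col.items():
        truth[f"planted_log2cpm.{name}"] = pop[:, j] - np.where(planted_mask, 0.0, shift)
    return cm, truth


def truth_summary(truth: pd.DataFrame) -> dict[str, int]:
    """Class counts of a truth table; signature classes partition the genes."""
    out = {
        f"signature.{cls}": int((truth["signature_class"] == cls).sum())
        for cls in (SIGNATURE_NULL, SIGNATURE_UP, SIGNATURE_DOWN)
    }
    out["private"] = int(truth["is_private"].sum())
    out["thymus_enriched"] = int(truth["thymus_enriched"].sum())
    for cell in TRAJECTORY_CELLS:
        out[f"trajectory.{cell}"] = int((truth["trajectory_class"] == cell).sum())
    out["n_genes"] = int(len(truth))
    return out


def synthetic_gene_sets(
    truth: pd.DataFrame,
    n_null_sets: int = 20,
    set_size: int = 50,
    seed: int = 0,
) -> GeneSetCollection:
    """A small gene-set collection for exercising the enrichment stage.

    One planted set drawn from the up-regulated truth class plus
    ``n_null_sets`` sets of genes drawn uniformly from the whole universe.
    """
    rng = np.random.default_rng(seed)
    genes = np.asarray(truth.index, dtype=object)
    up = np.asarray(truth.index[truth["signature_class"] == SIGNATURE_UP], dtype=object)
    sets: dict[str, GeneSet] = {}
    k = min(set_size, len(up))
    if k:
        members = frozenset(rng.choice(up, size=k, replace=False))
        sets["PLANTED_UP"] = GeneSet("PLANTED_UP", "planted up-regulated genes", members)
    for i in range(n_null_sets):
        members = frozenset(rng.choice(genes, size=min(set_size, len(genes)), replace=False))
        name = f"NULL_{i:02d}"
        sets[name] = GeneSet(name, "random gene set", members)
    return GeneSetCollection(sets=sets)
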