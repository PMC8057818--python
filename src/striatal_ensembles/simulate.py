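"""Synthetic smFISH sections and bulk 3'-RNA-seq counts with known ground truth.

The generator emulates the two data modalities of a cocaine-sensitization
study of the dorsal striatum:

* per-cell smFISH puncta tables -- cells scattered over a rectangular
  section split into a medial (MS) and a ventrolateral (VLS) subdomain,
  with a latent per-cell recruitment flag driving negative-binomial (NB)
  puncta counts for four immediate-early genes (IEGs: Arc, Egr2, Fos,
  Nr4a1) and mutually exclusive Drd1+/Drd2+ receptor classes;
* gene x sample bulk count matrices over a 0/1/2/4 h time course for
  acute / repeated / challenge cocaine experiences, with a subset of
  genes carrying a planted triangular induction profile.

Every simulation returns a :class:`GroundTruth` alongside the table so
that downstream stages support parameter-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

IEG_GENES = ("Arc", "Egr2", "Fos", "Nr4a1")
RECEPTOR_GENES = ("Drd1", "Drd2")
CONDITIONS = ("control", "acute", "repeated", "challenge")
CELL_TYPES = ("Drd1", "Drd2", "other")
EXPERIENCES = ("acute", "repeated", "challenge")
TIMEPOINTS = (0, 1, 2, 4)


def _default_recruit_prob() -> dict:
    """Default (region, condition, cell_type) -> recruitment probability.

    Control reflects baseline (home-cage) ensemble activity; acute values
    follow the strong MS recruitment of both SPN types and the
    Drd1-enriched VLS recruitment; repeated exposure dampens acute
    recruitment by x0.5 and a challenge dose largely reinstates it (x0.9).
    """
    prob: dict = {}
    acute = {
        ("MS", "Drd1"): 0.46,
        ("MS", "Drd2"): 0.40,
        ("MS", "other"): 0.05,
        ("VLS", "Drd1"): 0.46,
        ("VLS", "Drd2"): 0.08,
        ("VLS", "other"): 0.05,
    }
    for (region, ctype), p in acute.items():
        prob[(region, "control", ctype)] = 0.13
        prob[(region, "acute", ctype)] = p
        prob[(region, "repeated", ctype)] = 0.5 * p
        prob[(region, "challenge", ctype)] = 0.9 * p
    return prob


@dataclass
class SectionSimParams:
    """Parameters of one simulated striatal section.

    Coordinates are in micrometres in a section-local frame with the
    origin at the top-left corner; the vertical line at
    ``region_split * width`` separates MS (left) from VLS (right).
    Inside the VLS the recruitment probability is scaled by a Gaussian
    bump ``exp(-d^2 / (2 hotspot_sd^2))`` around ``hotspot_center``.
    """

    n_cells: int = 5000
    arena: tuple[float, float] = (3000.0, 2000.0)
    region_split: float = 0.5
    hotspot_center: tuple[float, float] = (2250.0, 1000.0)
    hotspot_sd: float = 400.0
    recruit_prob: dict = field(default_factory=_default_recruit_prob)
    mu_bg: float = 0.8
    mu_ind: float = 18.0
    nb_size: float = 20.0
    receptor_mu_hi: float = 25.0
    receptor_mu_lo: float = 1.0
    celltype_props: tuple[float, float, float] = (0.45, 0.45, 0.10)
    independent_iegs: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not self.n_cells > 0:
            raise ValueError("n_cells must be positive")
        if not (np.isfinite(self.arena).all() and min(self.arena) > 0):
            raise ValueError("arena dimensions must be positive and finite")
        if not 0.0 < self.region_split < 1.0:
            raise ValueError("region_split must lie in (0, 1)")
        if not self.hotspot_sd > 0:
            raise ValueError("hotspot_sd must be positive")
        for key, p in self.recruit_prob.items():
            if not (np.isfinite(p) and 0.0 <= p <= 1.0):
                raise ValueError(f"recruit_prob[{key!r}] = {p} outside [0, 1]")
        if self.mu_ind <= self.mu_bg:
            raise ValueError("mu_ind must exceed mu_bg")
        if self.mu_bg < 0 or self.nb_size <= 0:
            raise ValueError("mu_bg must be >= 0 and nb_size > 0")
        props = np.asarray(self.celltype_props, dtype=float)
        if props.min() < 0 or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("celltype_props must be non-negative and sum to 1")


@dataclass
class BulkSimParams:
    """Parameters of a simulated bulk 3'-RNA-seq time-course experiment."""

    n_genes: int = 200
    n_induced: int = 20
    baseline_mu: np.ndarray | None = None  # per-gene NB mean; drawn if None
    dispersion: float | np.ndarray = 0.05  # NB alpha: var = mu + alpha mu^2
    peak_times: np.ndarray | None = None  # per induced gene in {1, 2, 4}
    fold_changes: float | np.ndarray = 4.0
    dampening: dict | None = None  # experience -> factor in (0, 1]
    library_sizes: np.ndarray | None = None  # per-sample scale factors
    replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_induced > self.n_genes:
            raise ValueError("n_induced cannot exceed n_genes")
        if self.n_genes <= 0 or self.n_induced < 0:
            raise ValueError("n_genes must be positive, n_induced non-negative")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        fc = np.atleast_1d(np.asarray(self.fold_changes, dtype=float))
        if (fc <= 1.0).any():
            raise ValueError("fold_changes must exceed 1")
        for exp, d in (self.dampening or {}).items():
            if not 0.0 < d <= 1.0:
                raise ValueError(f"dampening[{exp!r}] must lie in (0, 1]")


@dataclass
class GroundTruth:
    """Latent state of a simulation, keyed consistently with its table."""

    # smFISH side (indexed like the CellTable rows)
    recruited: np.ndarray | None = None  # latent z per cell
    recruit_prob: np.ndarray | None = None  # true per-cell probability
    cell_type: np.ndarray | None = None
    hotspot_center: tuple[float, float] | None = None
    hotspot_sd: float | None = None
    # bulk side (indexed like the CountMatrix genes)
    induced: np.ndarray | None = None  # per-gene flag
    peak_time: np.ndarray | None = None  # {1,2,4}; 0 for non-induced
    fold_change: np.ndarray | None = None  # 1.0 for non-induced
    library_sizes: np.ndarray | None = None
    dampening: dict | None = None

    def concat(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            recruited=np.concatenate([self.recruited, other.recruited]),
            recruit_prob=np.concatenate([self.recruit_prob, other.recruit_prob]),
            cell_type=np.concatenate([self.cell_type, other.cell_type]),
            hotspot_center=self.hotspot_center,
            hotspot_sd=self.hotspot_sd,
        )


def _nb_draw(rng: np.random.Generator, mu, size_param: float, n: int) -> np.ndarray:
    """NB draws parameterised by mean and size (var = mu + mu^2 / size)."""
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (n,))
    out = np.zeros(n, dtype=np.int64)
    pos = mu > 0
    if pos.any():
        p = size_param / (size_param + mu[pos])
        out[pos] = rng.negative_binomial(size_param, p)
    return out


def simulate_section(
    params: SectionSimParams,
    condition: str = "acute",
    section_id: str = "S0",
    mouse_id: str = "M0",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one section: a CellTable plus its latent ground truth.

    Cells are placed by a uniform spatial Poisson process over the arena,
    assigned a region by the vertical MS/VLS boundary and a mutually
    exclusive cell type; a single shared latent activation per cell drives
    all IEG counts (set ``independent_iegs`` for per-gene independent
    recruitment null models).
    """
    params.validate()
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(params.seed)
    n = params.n_cells
    width, height = params.arena

    x = rng.uniform(0.0, width, n)
    y = rng.uniform(0.0, height, n)
    region = np.where(x < params.region_split * width, "MS", "VLS")
    cell_type = rng.choice(CELL_TYPES, size=n, p=params.celltype_props)

    base = np.array(
        [params.recruit_prob.get((r, condition, c), 0.0) for r, c in zip(region, cell_type)]
    )
    cx, cy = params.hotspot_center
    bump = np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * params.hotspot_sd**2))
    prob = np.where(region == "VLS", base * bump, base)

    table = pd.DataFrame(
        {
            "section_id": section_id,
            "mouse_id": mouse_id,
            "condition": condition,
            "region": region,
            "x": x,
            "y": y,
        }
    )
    if params.independent_iegs:
        z_by_gene = {g: rng.random(n) < prob for g in IEG_GENES}
        z = z_by_gene[IEG_GENES[0]]
    else:
        z = rng.random(n) < prob
        z_by_gene = {g: z for g in IEG_GENES}
    for gene in IEG_GENES:
        mu = np.where(z_by_gene[gene], params.mu_ind, params.mu_bg)
        table[gene] = _nb_draw(rng, mu, params.nb_size, n)
    for receptor in RECEPTOR_GENES:
        mu = np.where(cell_type == receptor, params.receptor_mu_hi, params.receptor_mu_lo)
        table[receptor] = _nb_draw(rng, mu, params.nb_size, n)

    truth = GroundTruth(
        recruited=z.astype(bool),
        recruit_prob=prob,
        cell_type=cell_type,
        hotspot_center=params.hotspot_center,
        hotspot_sd=params.hotspot_sd,
    )
    return table, truth


def simulate_experiment(
    design: list[tuple[str, int]],
    params: SectionSimParams,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Concatenate sections for a multi-condition design.

    ``design`` lists (condition, n_sections) pairs; each section gets a
    distinct section_id and its own seed derived from ``params.seed``.
    Three sections per mouse, mirroring common smFISH replication.
    """
    if not design:
        raise ValueError("design must be non-empty")
    tables: list[pd.DataFrame] = []
    truth: GroundTruth | None = None
    seen: set[str] = set()
    counter = 0
    for condition, n_sections in design:
        for k in range(n_sections):
            sid = f"{condition}_s{k}"
            if sid in seen:
                raise ValueError(f"duplicate section_id {sid!r}")
            seen.add(sid)
            sec_params = replace(params, seed=params.seed + 1000 * counter + 1)
            mouse = f"{condition}_m{k // 3}"
            tab, t = simulate_section(sec_params, condition, sid, mouse)
            tables.append(tab)
            truth = t if truth is None else truth.concat(t)
            counter += 1
    return pd.concat(tables, ignore_index=True), truth


def _triangular_profile(peak: int, fc: float) -> dict[int, float]:
    """Fold factor at each time point: linear rise to (peak, fc), linear
    decay back to baseline at the end of the time course."""
    times = np.array(TIMEPOINTS, dtype=float)
    f = np.ones_like(times)
    rise = times <= peak
    f[rise] = 1.0 + (fc - 1.0) * times[rise] / peak
    if peak < times[-1]:
        fall = times > peak
        f[fall] = fc - (fc - 1.0) * (times[fall] - peak) / (times[-1] - peak)
    return {int(t): float(v) for t, v in zip(times, f)}


def simulate_counts(
    params: BulkSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a gene x sample NB count matrix over the time-course design.

    Samples cover every (experience, timepoint) cell with ``replicates``
    samples each; induced genes follow a triangular profile peaking at
    their assigned time, with a per-experience multiplicative dampening of
    the fold change. Returns (counts, sample metadata, ground truth).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    G, R = params.n_genes, params.replicates
    genes = [f"gene{i:04d}" for i in range(G)]

    baseline = (
        np.asarray(params.baseline_mu, dtype=float)
        if params.baseline_mu is not None
        else np.exp(rng.uniform(np.log(20.0), np.log(2000.0), G))
    )
    alpha = np.broadcast_to(np.asarray(params.dispersion, dtype=float), (G,))
    fc = np.broadcast_to(np.atleast_1d(np.asarray(params.fold_changes, dtype=float)),
                         (params.n_induced,))
    peaks = (
        np.asarray(params.peak_times)
        if params.peak_times is not None
        else rng.choice([1, 2, 4], size=params.n_induced)
    )
    dampening = params.dampening or {"acute": 1.0, "repeated": 0.6, "challenge": 0.9}

    induced = np.zeros(G, dtype=bool)
    induced[: params.n_induced] = True
    true_peak = np.zeros(G, dtype=int)
    true_peak[: params.n_induced] = peaks
    true_fc = np.ones(G)
    true_fc[: params.n_induced] = fc

    meta_rows = []
    for exp in EXPERIENCES:
        for t in TIMEPOINTS:
            for r in range(R):
                meta_rows.append({"sample_id": f"{exp}_{t}h_r{r}", "structure": "DS",
                                  "experience": exp, "timepoint": t})
    meta = pd.DataFrame(meta_rows)
    S = len(meta)
    lib = (
        np.asarray(params.library_sizes, dtype=float)
        if params.library_sizes is not None
        else np.exp(rng.normal(0.0, 0.15, S))
    )
    meta["usable_reads"] = 0  # filled after drawing counts

    counts = np.zeros((G, S), dtype=np.int64)
    profiles = {}
    for g in range(G):
        if induced[g]:
            key = (true_peak[g], true_fc[g])
            if key not in profiles:
                profiles[key] = _triangular_profile(*key)
            prof = profiles[key]
        else:
            prof = None
        for s in range(S):
            exp, t = meta.loc[s, "experience"], int(meta.loc[s, "timepoint"])
            f = 1.0
            if prof is not None and t > 0:
                f = 1.0 + (prof[t] - 1.0) * dampening[exp]
            mu = lib[s] * baseline[g] * f
            size_param = 1.0 / max(alpha[g], 1e-12)
            p = size_param / (size_param + mu)
            counts[g, s] = rng.negative_binomial(size_param, p)

    count_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                            columns=meta["sample_id"].tolist())
    meta["usable_reads"] = count_df.sum(axis=0).to_numpy() * 50  # counts are per-gene UMIs
    truth = GroundTruth(
        induced=induced, peak_time=true_peak, fold_change=true_fc,
        library_sizes=lib, dampening=dampening,
    )
    return count_df, meta, truth
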