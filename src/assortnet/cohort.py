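"""Synthetic cohort generator with planted nodal-assortativity effects.

Emulates the data structure of a three-stage cognitive-decline study
(SCI = subjective cognitive impairment controls, MCI = amnestic mild
cognitive impairment, ADD = early Alzheimer's disease dementia): 24/46/18
subjects with group-specific ages, each carrying a structural and a
functional connectome over a Schaefer-style 400-node parcellation.

Base networks are drawn from a degree-heterogeneous random-graph model with
a degree-similarity kernel that makes structural draws assortative (global
r > 0) and functional draws near-zero/disassortative, mirroring the
sNET/fNET dichotomy seen in real connectomes. Disease effects are planted
*topologically*: at designated "hypo" nodes, MCI and ADD subjects have edges
rewired toward hubs, inflating neighbor-degree disparity and lowering that
node's local assortativity r_i; at disjoint "hyper" nodes, ADD subjects are
rewired toward degree-similar partners, raising r_i. The rewiring budget per
node is calibrated so the induced shift in r_i equals ``effect_size`` times
the between-subject standard deviation of r_i at baseline — the effect is
realized through network topology exactly as the measure would detect it in
real data, never by editing the measure itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .connectome import (
    Connectome,
    make_node_labels,
    read_adjacency,
    read_node_labels,
    write_adjacency,
    write_node_labels,
)
from .exceptions import CohortIOError, ConfigError, InfeasibleConfigError

GROUPS = ("SCI", "MCI", "ADD")

__all__ = [
    "GROUPS",
    "SyntheticConfig",
    "Subject",
    "Cohort",
    "generate_cohort",
    "generate_bold_panel",
    "write_cohort",
    "read_cohort",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-emulating generator settings.

    Group sizes and age moments follow the study cohort (24 SCI / 46 MCI /
    18 ADD; ages 56.95±7.54, 62.04±9.78, 69.83±8.52 years, truncated to
    [40, 95]). ``effect_size`` is the target shift of nodal assortativity at
    planted nodes in units of its between-subject standard deviation.
    """

    group_sizes: tuple[int, int, int] = (24, 46, 18)
    age_params: tuple[tuple[float, float], ...] = ((56.95, 7.54), (62.04, 9.78), (69.83, 8.52))
    age_range: tuple[float, float] = (40.0, 95.0)
    node_count: int = 400
    hypo_nodes: tuple[int, ...] = (10, 60, 110, 160, 210)
    hyper_nodes: tuple[int, ...] = (35, 85, 135, 185, 235)
    effect_size: float = 1.0
    base_density: float = 0.10
    #: between-subject sd of the lognormal degree template (heterogeneity)
    degree_sigma: float = 0.45
    #: per-subject multiplicative jitter of the shared degree template
    degree_jitter: float = 0.10
    #: degree-similarity kernel strength per modality: positive = assortative
    structural_mixing: float = 2.5
    functional_mixing: float = -0.5
    #: structural weights ~ lognormal(mu, sigma) (fiber-count-like)
    structural_weight: tuple[float, float] = (3.5, 0.8)
    #: functional |weights| ~ uniform(lo, hi), sign positive with prob p_pos
    functional_weight: tuple[float, float, float] = (0.10, 0.40, 0.7)
    modalities: tuple[str, ...] = ("structural", "functional")
    #: scales each subject's planted effect by (1 + age_confound * z(age));
    #: 0 keeps ages independent of the network effect
    age_confound: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_sizes) != 3 or any(n < 2 for n in self.group_sizes):
            raise ConfigError("group_sizes must be three integers >= 2")
        overlap = set(self.hypo_nodes) & set(self.hyper_nodes)
        if overlap:
            raise ConfigError(f"hypo and hyper node sets must be disjoint; overlap {sorted(overlap)}")
        planted = set(self.hypo_nodes) | set(self.hyper_nodes)
        if any(v < 0 or v >= self.node_count for v in planted):
            raise ConfigError("planted node ids must lie in [0, node_count)")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if not 0 < self.base_density < 1:
            raise ConfigError("base_density must lie in (0, 1)")
        bad = [m for m in self.modalities if m not in ("structural", "functional")]
        if bad:
            raise ConfigError(f"unknown modalities {bad}")

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) if path.suffix in (".yaml", ".yml") else json.loads(path.read_text())
        for key in ("group_sizes", "hypo_nodes", "hyper_nodes", "age_range", "modalities",
                    "structural_weight", "functional_weight"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(tuple(x) if isinstance(x, list) else x for x in raw[key]) \
                    if key == "age_params" else tuple(raw[key])
        if "age_params" in raw:
            raw["age_params"] = tuple(tuple(p) for p in raw["age_params"])
        return cls(**raw)


@dataclass
class Subject:
    subject_id: str
    group: str
    age: float
    sex: str
    snet: Connectome | None = None
    fnet: Connectome | None = None

    def network(self, modality: str) -> Connectome:
        net = self.snet if modality == "structural" else self.fnet
        if net is None:
            raise CohortIOError(f"subject {self.subject_id} has no {modality} network")
        return net


@dataclass
class Cohort:
    subjects: list[Subject]
    node_labels: pd.DataFrame
    config: SyntheticConfig | None = None
    #: optional parcel x time BOLD panels, keyed by subject id
    bold_panels: dict | None = None

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age for s in self.subjects])

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    @property
    def node_count(self) -> int:
        return len(self.node_labels)

    def of_group(self, group: str) -> list[Subject]:
        return [s for s in self.subjects if s.group == group]


# ---------------------------------------------------------------------------
# fast internal topology helpers (dense binary matrices, no Connectome checks)

def _nodal_r(B: np.ndarray):
    """(r_i vector, delta vector, S=sum delta, r) on a binary adjacency.

    r is the Pearson correlation of endpoint degrees over the directed edge
    list, computed from degree moments (sum d^2, sum d^3, d'Bd) instead of an
    explicit edge list — algebraically identical, O(n^2).
    """
    d = B.sum(axis=1)
    m = B.shape[0]
    disparity = np.abs(d[None, :] - d[:, None])
    delta = np.where(d > 0, (B * disparity).sum(axis=1) / np.where(d > 0, d, 1.0), 0.0)
    S = delta.sum()
    n_dir = d.sum()
    if n_dir == 0:
        return np.full(m, np.nan), delta, S, float("nan")
    sx = (d ** 2).sum() / n_dir
    vx = (d ** 3).sum() / n_dir - sx * sx
    r = float((d @ B @ d / n_dir - sx * sx) / vx) if vx > 0 else float("nan")
    if S == 0:
        return np.full(m, np.nan), delta, S, r
    return (r + 1.0) / m - delta / S, delta, S, r


def _base_binary(t_subj: np.ndarray, density: float, mixing: float, rng: np.random.Generator) -> np.ndarray:
    """Degree-heterogeneous random graph with a degree-similarity kernel."""
    n = t_subj.size
    tbar = t_subj.mean()
    K = np.exp(-mixing * np.abs(t_subj[None, :] - t_subj[:, None]) / tbar)
    P = np.outer(t_subj, t_subj) * K
    iu = np.triu_indices(n, k=1)
    target_edges = density * n * (n - 1) / 2.0
    P = P * (target_edges / P[iu].sum())
    np.clip(P, 0.0, 0.95, out=P)
    upper = rng.random(iu[0].size) < P[iu]
    B = np.zeros((n, n))
    B[iu] = upper
    return B + B.T


def _draw_weight(modality: str, cfg: SyntheticConfig, rng: np.random.Generator, size: int):
    if modality == "structural":
        mu, sigma = cfg.structural_weight
        return rng.lognormal(mu, sigma, size)
    lo, hi, p_pos = cfg.functional_weight
    sign = np.where(rng.random(size) < p_pos, 1.0, -1.0)
    return sign * rng.uniform(lo, hi, size)


def _plant_node_calibrated(W: np.ndarray, v: int, target_r_shift: float, avoid: set[int],
                           modality: str, cfg: SyntheticConfig, rng: np.random.Generator) -> None:
    """Shift node v's local assortativity r_v by ``target_r_shift`` via rewiring.

    A first pass targets the linearized disparity change delta_v -> delta_v -
    S * target_r_shift; because each move also perturbs neighbor degrees (and
    through them the disparity normalization), the realized shift is then
    measured exactly and corrective passes absorb the residual.
    """
    r0 = _nodal_r((np.abs(W) > 0).astype(float))[0][v]
    for attempt in range(8):
        rv, _, S, _ = _nodal_r((np.abs(W) > 0).astype(float))
        residual = target_r_shift - (rv[v] - r0)
        if abs(residual) <= 0.05 * abs(target_r_shift):
            return
        _plant_node(W, v, -residual * S, avoid, modality, cfg, rng, strict=attempt == 0)


def _plant_node(W: np.ndarray, v: int, target: float, avoid: set[int],
                modality: str, cfg: SyntheticConfig, rng: np.random.Generator,
                strict: bool = True) -> float:
    """Rewire edges of node v to shift its neighbor-degree disparity delta_v.

    ``target`` is the desired change in delta_v: positive = attach toward
    hubs (hypo-assortativity), negative = attach toward degree-similar nodes
    (hyper-assortativity). Node v's own degree is preserved: every move
    deletes one edge (v,u) and adds one edge (v,h). Returns the realized
    change; raises InfeasibleConfigError if less than half the requested
    shift is achievable.
    """
    B = (np.abs(W) > 0).astype(float)
    d = B.sum(axis=1)
    dv = d[v]
    if dv == 0:
        raise InfeasibleConfigError(f"planted node {v} is isolated; raise base_density")
    neigh = set(np.nonzero(B[v])[0].tolist()) - avoid
    non = set(range(W.shape[0])) - set(np.nonzero(B[v])[0].tolist()) - avoid - {v}
    realized = 0.0
    remaining = target
    sign = 1.0 if target >= 0 else -1.0
    for _ in range(int(dv)):
        if sign * remaining <= 0.02 * abs(target) or not neigh or not non:
            break
        nl = np.fromiter(neigh, dtype=int)
        hl = np.fromiter(non, dtype=int)
        # free the least useful edge: the least-disparate neighbor when we
        # want more disparity, the most-disparate when we want less
        disp_u = np.abs(d[nl] - dv)
        u = int(nl[np.argmin(disp_u) if sign > 0 else np.argmax(disp_u)])
        gains = (np.abs(d[hl] + 1 - dv) - abs(d[u] - dv)) / dv
        useful = gains * sign > 0
        if not useful.any():
            break
        g, h_cand = gains[useful], hl[useful]
        # pick the move that lands closest to the remaining target without
        # large overshoot; if none reaches it, take the biggest step
        reach = g * sign >= sign * remaining
        if reach.any():
            pick = np.argmin(np.abs(g[reach] - remaining))
            h, gain = int(h_cand[reach][pick]), float(g[reach][pick])
        else:
            pick = np.argmax(g * sign)
            h, gain = int(h_cand[pick]), float(g[pick])
        w_new = float(_draw_weight(modality, cfg, rng, 1)[0])
        W[v, u] = W[u, v] = 0.0
        W[v, h] = W[h, v] = w_new
        d[u] -= 1
        d[h] += 1
        neigh.discard(u)
        neigh.add(h)
        non.discard(h)
        non.add(u)
        realized += gain
        remaining -= gain
    if strict and abs(realized) < 0.5 * abs(target):
        raise InfeasibleConfigError(
            f"node {v}: only {realized:.3g} of requested disparity shift {target:.3g} "
            f"realizable at density {cfg.base_density}; raise base_density or lower effect_size"
        )
    return realized


# ---------------------------------------------------------------------------

def generate_cohort(config: SyntheticConfig | None = None, **overrides) -> Cohort:
    """Draw a full synthetic cohort; deterministic given ``config.seed``."""
    cfg = config or SyntheticConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    root = np.random.SeedSequence(cfg.seed)
    ss_template, ss_ages, ss_nets, ss_plant = root.spawn(4)
    rng_t = np.random.default_rng(ss_template)
    n_total = sum(cfg.group_sizes)

    # shared degree template: a parcel's expected connectivity is a property
    # of the atlas position, consistent across subjects
    template = rng_t.lognormal(0.0, cfg.degree_sigma, cfg.node_count)
    planted = list(cfg.hypo_nodes) + list(cfg.hyper_nodes)
    if planted and cfg.effect_size > 0:
        # planted nodes get mid-range expected connectivity so the disparity
        # rewiring is realizable in either direction at every seed
        template[planted] = np.median(template)

    rng_a = np.random.default_rng(ss_ages)
    lo, hi = cfg.age_range
    groups, ages, sexes = [], [], []
    for g, n_g, (mu, sd) in zip(GROUPS, cfg.group_sizes, cfg.age_params):
        a, b = (lo - mu) / sd, (hi - mu) / sd
        ages.extend(truncnorm.rvs(a, b, loc=mu, scale=sd, size=n_g, random_state=rng_a))
        groups.extend([g] * n_g)
        sexes.extend(["F" if i < n_g // 2 else "M" for i in range(n_g)])

    mixing = {"structural": cfg.structural_mixing, "functional": cfg.functional_mixing}
    net_seeds = ss_nets.spawn(n_total * 2)
    nets: dict[str, list[np.ndarray]] = {m: [] for m in cfg.modalities}
    for s_idx in range(n_total):
        for m_idx, modality in enumerate(cfg.modalities):
            rng = np.random.default_rng(net_seeds[s_idx * 2 + m_idx])
            t_subj = template * np.exp(rng.normal(0.0, cfg.degree_jitter, cfg.node_count))
            B = _base_binary(t_subj, cfg.base_density, mixing[modality], rng)
            iu = np.triu_indices(cfg.node_count, k=1)
            mask = B[iu] > 0
            w = np.zeros(iu[0].size)
            w[mask] = _draw_weight(modality, cfg, rng, int(mask.sum()))
            W = np.zeros_like(B)
            W[iu] = w
            nets[modality].append(W + W.T)

    _plant_effects(nets, cfg, groups, ages, ss_plant)

    labels = make_node_labels(cfg.node_count)
    subjects = []
    for s_idx in range(n_total):
        kw = {}
        if "structural" in cfg.modalities:
            kw["snet"] = Connectome(nets["structural"][s_idx], "structural", labels)
        if "functional" in cfg.modalities:
            kw["fnet"] = Connectome(nets["functional"][s_idx], "functional", labels)
        subjects.append(Subject(f"sub-{s_idx + 1:03d}", groups[s_idx], float(ages[s_idx]), sexes[s_idx], **kw))
    return Cohort(subjects, labels, cfg)


def _plant_effects(nets, cfg: SyntheticConfig, groups, ages, ss_plant) -> None:
    """Apply calibrated hypo/hyper rewiring in place."""
    if cfg.effect_size == 0 or not (cfg.hypo_nodes or cfg.hyper_nodes):
        return
    planted = list(cfg.hypo_nodes) + list(cfg.hyper_nodes)
    avoid = set(planted)
    groups = np.asarray(groups)
    ages = np.asarray(ages)
    age_scale = np.ones(len(groups))
    if cfg.age_confound:
        z = (ages - ages.mean()) / ages.std()
        age_scale = np.clip(1.0 + cfg.age_confound * z, 0.0, None)
    plant_seeds = np.random.SeedSequence(ss_plant.entropy, spawn_key=(0,)).spawn(len(groups) * 2)

    def _pooled_sd(a, b):
        return float(np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0))

    for m_idx, modality in enumerate(cfg.modalities):
        Ws = nets[modality]
        # baseline r_i at planted nodes for every subject, before any rewiring
        base = np.stack([_nodal_r((np.abs(W) > 0).astype(float))[0][planted] for W in Ws])
        col = {v: i for i, v in enumerate(planted)}
        sci, mci, add = (base[groups == g] for g in GROUPS)
        # effect_size is the target *group-mean* contrast in pooled-sd units,
        # so the per-subject shift absorbs the baseline sampling fluctuation
        # of the group means at each planted node
        targets: dict[str, dict[int, float]] = {"MCI": {}, "ADD": {}}
        for v in cfg.hypo_nodes:  # r_i decreases from SCI level, for MCI and ADD
            j = col[v]
            m_sci = sci[:, j].mean()
            targets["MCI"][v] = (m_sci - cfg.effect_size * _pooled_sd(sci[:, j], mci[:, j])) - mci[:, j].mean()
            targets["ADD"][v] = (m_sci - cfg.effect_size * _pooled_sd(sci[:, j], add[:, j])) - add[:, j].mean()
        for v in cfg.hyper_nodes:  # r_i increases from (unshifted) MCI level, ADD only
            j = col[v]
            targets["ADD"][v] = (mci[:, j].mean() + cfg.effect_size * _pooled_sd(mci[:, j], add[:, j])) - add[:, j].mean()
        for s_idx, g in enumerate(groups):
            if g == "SCI":
                continue
            rng = np.random.default_rng(plant_seeds[s_idx * 2 + m_idx])
            W = Ws[s_idx]
            scale = age_scale[s_idx]
            for v, shift in targets[g].items():
                _plant_node_calibrated(W, v, scale * shift, avoid, modality, cfg, rng)


def generate_bold_panel(config: SyntheticConfig, subject: Subject,
                        timepoints: int = 200, seed: int | None = None) -> np.ndarray:
    """Draw a parcels x timepoints Gaussian panel whose partial-correlation
    structure matches the subject's functional network.

    The precision matrix is built as I - W (so the analytic partial
    correlation of pair (i, j) equals W_ij), diagonally loaded to keep the
    smallest eigenvalue >= 0.05, and renormalized to unit diagonal; support
    is preserved, magnitudes shrink proportionally under loading.
    """
    W = subject.network("functional").adjacency
    n = W.shape[0]
    M = np.eye(n) - W
    lam = np.linalg.eigvalsh(M)[0]
    if lam < 0.05:
        M = M + (0.05 - lam) * np.eye(n)
    dinv = 1.0 / np.sqrt(np.diagonal(M))
    omega = M * np.outer(dinv, dinv)
    cov = np.linalg.inv(omega)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    L = np.linalg.cholesky((cov + cov.T) / 2.0)
    return (L @ rng.standard_normal((n, timepoints)))


# ---------------------------------------------------------------------------
# directory round trip

def write_cohort(cohort: Cohort, directory: str | Path, fmt: str = "csv") -> None:
    """Write ``participants.tsv``, ``node_labels.tsv`` and per-subject
    ``snet/``, ``fnet/`` adjacency files (CSV or MTX)."""
    if fmt not in ("csv", "mtx"):
        raise CohortIOError(f"unknown adjacency format {fmt!r}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = [(s.subject_id, s.group, repr(s.age), s.sex) for s in cohort.subjects]
    pd.DataFrame(rows, columns=["subject_id", "group", "age", "sex"]).to_csv(
        directory / "participants.tsv", sep="\t", index=False)
    write_node_labels(cohort.node_labels, directory / "node_labels.tsv")
    for sub, attr in (("snet", "snet"), ("fnet", "fnet")):
        if any(getattr(s, attr) is not None for s in cohort.subjects):
            (directory / sub).mkdir(exist_ok=True)
            for s in cohort.subjects:
                net = getattr(s, attr)
                if net is not None:
                    write_adjacency(net.adjacency, directory / sub / f"{s.subject_id}.{fmt}")
    if cohort.bold_panels:
        (directory / "bold").mkdir(exist_ok=True)
        for sid, panel in cohort.bold_panels.items():
            np.savetxt(directory / "bold" / f"{sid}.tsv", np.asarray(panel, dtype=float),
                       delimiter="\t", fmt="%.17g")


def read_cohort(directory: str | Path) -> Cohort:
    directory = Path(directory)
    part = directory / "participants.tsv"
    if not part.exists():
        raise CohortIOError(f"no participants.tsv in {directory}")
    lines = part.read_text().splitlines()
    header = lines[0].split("\t")
    if header[:4] != ["subject_id", "group", "age", "sex"]:
        raise CohortIOError(f"{part}:1: expected header subject_id/group/age/sex, got {header}")
    labels = read_node_labels(directory / "node_labels.tsv")
    subjects = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise CohortIOError(f"{part}:{lineno}: expected 4 tab-separated fields, got {len(fields)}")
        sid, group, age_s, sex = fields
        if group not in GROUPS:
            raise CohortIOError(f"{part}:{lineno}: unknown group {group!r}")
        try:
            age = float(age_s)
        except ValueError:
            raise CohortIOError(f"{part}:{lineno}: age {age_s!r} is not a number") from None
        nets = {}
        for sub, modality in (("snet", "structural"), ("fnet", "functional")):
            d = directory / sub
            if d.is_dir():
                hits = sorted(d.glob(f"{sid}.*"))
                if not hits:
                    raise CohortIOError(f"missing {sub} adjacency file for subject {sid}")
                nets[sub] = Connectome(read_adjacency(hits[0]), modality, labels)
        subjects.append(Subject(sid, group, age, sex, nets.get("snet"), nets.get("fnet")))
    bold_dir = directory / "bold"
    panels = None
    if bold_dir.is_dir():
        panels = {p.stem: np.loadtxt(p, delimiter="\t", ndmin=2)
                  for p in sorted(bold_dir.glob("*.tsv"))}
    return Cohort(subjects, labels, bold_panels=panels)
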