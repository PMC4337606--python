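"""Synthetic blastoderm embryos with known ground-truth expression boundaries.

The generator emulates lateral-view embryos of the kind produced by
colorimetric in situ hybridisation: broad gap-gene expression domains with
sigmoidal edges, staggered along the antero-posterior (A-P) axis, whose
boundary positions drift anteriorly across developmental time classes.
Every embryo carries its generating parameters (realised edge positions,
knock-down efficacy, seed), so the whole measurement pipeline can be
validated against known truth without any external data.

Positions are percent egg length (%EL), 0 = anterior pole. Intensity is
dimensionless in [0, ~1.2].
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .profiles import IntensityProfile
from .timeclasses import TIME_CLASSES, class_index, sort_classes

__all__ = [
    "DomainSpec",
    "DynamicsTable",
    "Effect",
    "PerturbationSpec",
    "SyntheticEmbryo",
    "make_profile",
    "make_embryo_image",
    "sample_cohort",
    "cohort_truth_table",
    "cohort_boundary_table",
    "default_wildtype_dynamics",
]


# --------------------------------------------------------------------------
# domain and dynamics specifications
# --------------------------------------------------------------------------

VALID_DOMAIN_IDS = {
    "anterior", "central", "abdominal", "posterior", "head_patch",
    "head_stripe", "pole",
}


@dataclass(frozen=True)
class DomainSpec:
    """One expression domain: a plateau between two sigmoidal edges."""

    gene: str
    domain_id: str
    a_edge: float
    p_edge: float
    amplitude: float = 1.0
    edge_steepness: float = 1.0

    def __post_init__(self):
        if self.domain_id not in VALID_DOMAIN_IDS:
            raise ValueError(f"unknown domain_id {self.domain_id!r}")
        if not (0.0 <= self.a_edge <= self.p_edge <= 100.0):
            raise ValueError(
                f"need 0 <= a_edge <= p_edge <= 100, got "
                f"({self.a_edge}, {self.p_edge})"
            )
        if not (0.0 < self.amplitude <= 1.0):
            raise ValueError("amplitude must lie in (0, 1]")
        if self.edge_steepness <= 0.0:
            raise ValueError("edge_steepness must be positive")


class DynamicsTable:
    """Ground-truth boundary trajectories: per (gene, domain, edge, time
    class) a median position (%EL) and a between-embryo s.d. (%EL).

    Positions printed in the reference description of *M. abdita* wild-type
    expression anchor the default table; classes in between anchors are
    linearly interpolated and flagged ``interpolated``.
    """

    COLUMNS = ["gene", "domain_id", "edge", "time_class", "position", "sd",
               "interpolated"]

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"dynamics table missing columns {sorted(missing)}")
        tab = table[self.COLUMNS].copy()
        for tc in tab["time_class"]:
            class_index(tc)
        if ((tab["position"] < 0) | (tab["position"] > 100)).any():
            raise ValueError("positions must lie in [0, 100]")
        if (tab["sd"] < 0).any():
            raise ValueError("s.d. must be non-negative")
        self.table = tab.reset_index(drop=True)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_anchors(
        cls,
        anchors: dict[tuple[str, str, str], Sequence[tuple[str, float]]],
        sd: float = 1.0,
        pole_sd: float = 0.0,
    ) -> "DynamicsTable":
        """Build a table from sparse (time_class, position) anchor lists.

        Classes between consecutive anchors are linearly interpolated on the
        time-class index and flagged. Edges pinned at a pole (0 or 100) get
        ``pole_sd`` instead of ``sd``.
        """
        rows = []
        for (gene, domain_id, edge), pts in anchors.items():
            pts = sorted(pts, key=lambda p: class_index(p[0]))
            idx = np.array([class_index(tc) for tc, _ in pts])
            pos = np.array([p for _, p in pts], dtype=float)
            anchor_set = set(idx.tolist())
            for i in range(idx[0], idx[-1] + 1):
                p = float(np.interp(i, idx, pos))
                at_pole = p in (0.0, 100.0)
                rows.append({
                    "gene": gene, "domain_id": domain_id, "edge": edge,
                    "time_class": TIME_CLASSES[i], "position": p,
                    "sd": pole_sd if at_pole else sd,
                    "interpolated": i not in anchor_set,
                })
        return cls(pd.DataFrame(rows))

    # -- access ------------------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return sorted(self.table["gene"].unique())

    def time_classes(self) -> list[str]:
        return sort_classes(self.table["time_class"].unique())

    def cells_at(self, gene: str, time_class: str) -> pd.DataFrame:
        t = self.table
        return t[(t["gene"] == gene) & (t["time_class"] == time_class)]

    def position(self, gene: str, domain_id: str, edge: str,
                 time_class: str) -> float:
        t = self.table
        sel = t[(t["gene"] == gene) & (t["domain_id"] == domain_id)
                & (t["edge"] == edge) & (t["time_class"] == time_class)]
        if sel.empty:
            raise KeyError((gene, domain_id, edge, time_class))
        return float(sel["position"].iloc[0])

    def restrict(self, time_classes: Iterable[str] | None = None,
                 genes: Iterable[str] | None = None) -> "DynamicsTable":
        t = self.table
        if time_classes is not None:
            t = t[t["time_class"].isin(list(time_classes))]
        if genes is not None:
            t = t[t["gene"].isin(list(genes))]
        return DynamicsTable(t)


# Anchor positions (%EL) for the four trunk gap genes in the M. abdita
# wild type. Non-anchored classes are linearly interpolated. A position of
# 0/100 means the domain abuts the respective pole.
_MAB_TRUNK_ANCHORS: dict[tuple[str, str, str], list[tuple[str, float]]] = {
    # anterior hb: from the anterior pole to a posterior boundary at 56%
    # (C11) shifting anteriorly by 8 %EL to 48% at T8
    ("hb", "anterior", "anterior"): [("C11", 0.0), ("T8", 0.0)],
    ("hb", "anterior", "posterior"): [("C11", 56.0), ("T8", 48.0)],
    # posterior hb: appears around C12/13 from 90% to the pole; anterior
    # border shifts to 84% by T2 and 72% by T8; pole retraction completes
    # only at T8, leaving a 72-84% domain
    ("hb", "posterior", "anterior"): [("C12", 90.0), ("C13", 90.0),
                                      ("T2", 84.0), ("T8", 72.0)],
    ("hb", "posterior", "posterior"): [("C12", 100.0), ("T7", 100.0),
                                       ("T8", 84.0)],
    # central Kr: 40-63% at C12, narrowing to 37-51% at T8 (anterior edge
    # shifts 3 %EL, posterior edge 12 %EL)
    ("Kr", "central", "anterior"): [("C12", 40.0), ("T8", 37.0)],
    ("Kr", "central", "posterior"): [("C12", 63.0), ("T8", 51.0)],
    # anterior gt stripe: 14-34% at C12, 15-35% from C13 on, posterior
    # boundary essentially stationary
    ("gt", "anterior", "anterior"): [("C12", 14.0), ("C13", 15.0),
                                     ("T8", 15.0)],
    ("gt", "anterior", "posterior"): [("C12", 34.0), ("C13", 35.0),
                                      ("T8", 35.0)],
    # posterior gt: from 73% (C12) / 72% (C13) to the pole; retracts to 86%
    # by T1 and narrows to 62-71% at T8
    ("gt", "posterior", "anterior"): [("C12", 73.0), ("C13", 72.0),
                                      ("T8", 62.0)],
    ("gt", "posterior", "posterior"): [("C12", 100.0), ("C13", 100.0),
                                       ("T1", 86.0), ("T8", 71.0)],
    # abdominal kni: 61-78% at C12; during C14A the anterior edge shifts
    # 4 %EL and the posterior edge 8 %EL
    ("kni", "abdominal", "anterior"): [("C12", 61.0), ("T1", 61.0),
                                       ("T8", 57.0)],
    ("kni", "abdominal", "posterior"): [("C12", 78.0), ("T1", 78.0),
                                        ("T8", 70.0)],
}


def default_wildtype_dynamics(sd: float = 1.0) -> DynamicsTable:
    """The packaged wild-type trajectories for the trunk gap genes
    (*hb*, *Kr*, *gt*, *kni*), anchored at the printed positions."""
    return DynamicsTable.from_anchors(_MAB_TRUNK_ANCHORS, sd=sd)


# --------------------------------------------------------------------------
# perturbations
# --------------------------------------------------------------------------

MODES = {"displace", "expand", "retraction_failure", "absent", "delay"}


@dataclass(frozen=True)
class Effect:
    """One consequence of a knock-down on one boundary / domain.

    ``max_delta`` is the displacement (%EL) at full efficacy; realised
    displacement scales with the embryo's efficacy. ``threshold`` is the
    efficacy above which all-or-none modes (absent, retraction_failure)
    trigger. ``direction`` (+1 posterior, -1 anterior) only matters for
    ``displace``.
    """

    gene: str
    domain_id: str
    edge: str
    mode: str
    max_delta: float = 0.0
    direction: int = 1
    threshold: float = 0.5

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.max_delta < 0:
            raise ValueError("max_delta must be >= 0")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must lie in [0, 1]")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be -1 or +1")


@dataclass(frozen=True)
class PerturbationSpec:
    """An RNAi knock-down: the targeted gene plus its effects on the
    expression of (other) genes, with per-embryo efficacy variability.

    ``efficacy`` is ("beta", a, b) for a Beta(a, b) draw on [0, 1], or
    ("point", v) for a fixed value. Per-embryo variation in knock-down
    strength produces a graded severity range across the cohort, the
    phenotypic analogue of an allelic series.
    """

    target_gene: str
    effects: tuple[Effect, ...] = ()
    efficacy: tuple = ("beta", 2.0, 2.0)

    def __post_init__(self):
        object.__setattr__(self, "effects", tuple(self.effects))
        kind = self.efficacy[0]
        if kind == "beta":
            _, a, b = self.efficacy
            if a <= 0 or b <= 0:
                raise ValueError("Beta parameters must be positive")
        elif kind == "point":
            _, v = self.efficacy
            if not (0.0 <= v <= 1.0):
                raise ValueError("point efficacy must lie in [0, 1]")
        else:
            raise ValueError(f"unknown efficacy distribution {kind!r}")

    def draw_efficacy(self, rng: np.random.Generator) -> float:
        if self.efficacy[0] == "beta":
            return float(rng.beta(self.efficacy[1], self.efficacy[2]))
        return float(self.efficacy[1])

    def effects_on(self, gene: str) -> list[Effect]:
        return [e for e in self.effects if e.gene == gene]


# --------------------------------------------------------------------------
# profile synthesis
# --------------------------------------------------------------------------

def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def make_profile(
    domains: Sequence[DomainSpec],
    noise_sd: float = 0.0,
    baseline: float = 0.0,
    n_points: int = 100,
    seed: int | None = None,
    embryo_id: str = "synthetic",
    gene: str | None = None,
    time_class: str | None = None,
) -> tuple[IntensityProfile, list[dict]]:
    """Render a 1-D intensity profile from domain specs.

    intensity(x) = baseline + sum_d A_d * s((x - a_d)/w_d) * s((p_d - x)/w_d)
    plus Gaussian noise, clipped to [0, 1.2]; s is the logistic function.
    Returns the profile and a ground-truth record per edge. Same-gene
    domains whose plateaus merge (overlapping extents) are flagged rather
    than rejected.
    """
    if n_points < 50:
        raise ValueError("n_points must be >= 50")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    x = (np.arange(n_points) + 0.5) * (100.0 / n_points)
    values = np.full(n_points, float(baseline))
    for d in domains:
        values = values + d.amplitude * (
            _logistic((x - d.a_edge) / d.edge_steepness)
            * _logistic((d.p_edge - x) / d.edge_steepness)
        )
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, n_points)
    values = np.clip(values, 0.0, 1.2)

    truth: list[dict] = []
    ordered = sorted(domains, key=lambda d: d.a_edge)
    for i, d in enumerate(ordered):
        merged = any(
            other is not d and other.gene == d.gene
            and other.a_edge <= d.p_edge and d.a_edge <= other.p_edge
            for other in ordered
        )
        for edge, pos in (("anterior", d.a_edge), ("posterior", d.p_edge)):
            truth.append({
                "domain_id": d.domain_id, "edge": edge, "position": pos,
                "merged": merged, "absent": False,
            })
    profile = IntensityProfile(
        positions=x, values=values, gene=gene or (domains[0].gene if domains else "none"),
        embryo_id=embryo_id, time_class=time_class,
    )
    return profile, truth


# --------------------------------------------------------------------------
# embryo rendering
# --------------------------------------------------------------------------

@dataclass
class SyntheticEmbryo:
    """One generated embryo: ground truth plus (optionally) a rendered
    profile and/or image."""

    embryo_id: str
    gene: str
    time_class: str
    ground_truth: list[dict]
    seed: int | None = None
    perturbed: str | None = None
    efficacy: float | None = None
    profile: IntensityProfile | None = None
    image: np.ndarray | None = None
    mask: np.ndarray | None = None
    pole_intensity: dict = field(default_factory=dict)


def make_embryo_image(
    profile: IntensityProfile,
    shape: tuple[int, int] = (120, 260),
    dv_modulation: Callable[[np.ndarray], np.ndarray] | None = None,
    seed: int | None = None,
    rotation_deg: float = 0.0,
    noise_sd: float = 0.0,
    anterior_left: bool = True,
) -> SyntheticEmbryo:
    """Render a lateral-view embryo: an elliptical mask whose interior
    intensity follows ``profile`` along the A-P axis, optionally modulated
    along D-V (``dv_modulation`` maps the signed D-V fraction in [-1, 1] to
    a multiplier) and rotated in the image plane.

    Raises if the geometry is too small for a 10% D-V midline strip to
    span at least 3 pixel rows.
    """
    h, w = shape
    rng = np.random.default_rng(seed)
    theta = np.deg2rad(rotation_deg)
    # semi-axes from the frame, shrunk so the rotated bounding box fits
    c, s = np.cos(theta), np.sin(theta)
    a, b = 0.46 * w, 0.38 * h
    half_w = np.hypot(a * c, b * s)
    half_h = np.hypot(a * s, b * c)
    scale = 0.98 * min(1.0, (w / 2) / half_w, (h / 2) / half_h)
    a, b = a * scale, b * scale
    if 0.10 * 2 * b < 3:
        raise ValueError(
            "degenerate shape: 10% D-V strip would span fewer than 3 pixel rows"
        )
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rows, cols = np.mgrid[0:h, 0:w]
    dx, dy = cols - cx, rows - cy
    u = (dx * np.cos(theta) + dy * np.sin(theta)) / a    # A-P, in [-1, 1]
    v = (-dx * np.sin(theta) + dy * np.cos(theta)) / b   # D-V, in [-1, 1]
    mask = (u ** 2 + v ** 2) <= 1.0
    ap = (u + 1.0) / 2.0 * 100.0
    if not anterior_left:
        ap = 100.0 - ap
    img = np.zeros(shape, dtype=float)
    inside = mask
    img[inside] = np.interp(ap[inside], profile.positions, profile.values)
    if dv_modulation is not None:
        img[inside] *= np.asarray(dv_modulation(v[inside]), dtype=float)
    if noise_sd > 0:
        img[inside] += rng.normal(0.0, noise_sd, int(inside.sum()))
    img = np.clip(img, 0.0, 1.2)
    return SyntheticEmbryo(
        embryo_id=profile.embryo_id, gene=profile.gene,
        time_class=profile.time_class or "T1",
        ground_truth=[], seed=seed, profile=profile,
        image=img, mask=mask.astype(np.uint8),
    )


# --------------------------------------------------------------------------
# cohort sampling
# --------------------------------------------------------------------------

_DOMAIN_FOR_GENE = {
    ("hb", "anterior"), ("hb", "posterior"), ("Kr", "central"),
    ("gt", "anterior"), ("gt", "posterior"), ("kni", "abdominal"),
}


def _realise_embryo_edges(
    dynamics: DynamicsTable,
    gene: str,
    time_class: str,
    rng: np.random.Generator,
    perturbation: PerturbationSpec | None,
    efficacy: float | None,
) -> tuple[list[dict], dict]:
    """Draw one embryo's edge positions for one stained gene."""
    cells = dynamics.cells_at(gene, time_class)
    truth: list[dict] = []
    pole_intensity: dict[str, float] = {}
    by_domain: dict[str, dict[str, pd.Series]] = {}
    for _, row in cells.iterrows():
        by_domain.setdefault(row["domain_id"], {})[row["edge"]] = row

    for domain_id, edges in by_domain.items():
        effects = (perturbation.effects_on(gene) if perturbation else [])
        effects = [e for e in effects if e.domain_id == domain_id]
        if any(e.mode == "absent" and efficacy >= e.threshold for e in effects):
            for edge in edges:
                truth.append({"domain_id": domain_id, "edge": edge,
                              "position": np.nan, "absent": True,
                              "mode": "absent"})
            pole_intensity[domain_id] = 0.0
            continue
        positions: dict[str, float] = {}
        modes: dict[str, str] = {}
        for edge, row in edges.items():
            pos = float(row["position"])
            sd = float(row["sd"])
            draw = rng.normal(pos, sd) if sd > 0 else pos
            for e in effects:
                if e.edge != edge:
                    continue
                if e.mode == "displace":
                    draw += efficacy * e.max_delta * e.direction
                    modes[edge] = "displace"
                elif e.mode == "expand":
                    out = -1.0 if edge == "anterior" else 1.0
                    draw += efficacy * e.max_delta * out
                    modes[edge] = "expand"
                elif e.mode == "delay":
                    tcs = dynamics.table
                    traj = tcs[(tcs["gene"] == gene)
                               & (tcs["domain_id"] == domain_id)
                               & (tcs["edge"] == edge)]
                    first = traj.iloc[0]["position"]
                    draw = (1 - efficacy) * draw + efficacy * float(first)
                    modes[edge] = "delay"
                elif e.mode == "retraction_failure":
                    pole = 100.0 if pos > 50 else 0.0
                    if efficacy >= e.threshold:
                        draw = pole
                        pole_intensity[domain_id] = 0.5 + 0.49 * min(
                            1.0, (efficacy - e.threshold) / max(1e-9, 1 - e.threshold))
                        modes[edge] = "retraction_failure"
                    elif efficacy >= 0.5 * e.threshold:
                        draw = draw + (pole - draw) * 0.5
                        pole_intensity[domain_id] = 0.25 + 0.24 * (
                            (efficacy - 0.5 * e.threshold) / max(1e-9, 0.5 * e.threshold))
                        modes[edge] = "partial_retraction"
            positions[edge] = float(np.clip(draw, 0.0, 100.0))
        if "anterior" in positions and "posterior" in positions:
            if positions["anterior"] > positions["posterior"]:
                mid = 0.5 * (positions["anterior"] + positions["posterior"])
                positions["anterior"] = positions["posterior"] = mid
        for edge, p in positions.items():
            truth.append({"domain_id": domain_id, "edge": edge,
                          "position": p, "absent": False,
                          "mode": modes.get(edge, "none")})
        if domain_id not in pole_intensity:
            post = positions.get("posterior", 0.0)
            pole_intensity[domain_id] = 1.0 if post >= 95.0 else 0.0
    return truth, pole_intensity


def sample_cohort(
    dynamics: DynamicsTable,
    n_per_class: int,
    perturbation: PerturbationSpec | None = None,
    seed: int | None = None,
    time_classes: Sequence[str] | None = None,
    genes: Sequence[str] | None = None,
    render: str = "none",
    profile_noise_sd: float = 0.05,
    edge_steepness: float = 1.0,
) -> list[SyntheticEmbryo]:
    """Sample a cohort of embryos, ``n_per_class`` per stained gene per
    time class. Edge positions are drawn Normal(median, s.d.), truncated
    to [0, 100]; a perturbation draws one efficacy per embryo and scales
    its effects by it.

    ``render='none'`` keeps embryos at boundary level (fast);
    ``'profile'`` additionally synthesises 1-D intensity profiles;
    ``'image'`` renders full 2-D embryos.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if render not in {"none", "profile", "image"}:
        raise ValueError("render must be 'none', 'profile' or 'image'")
    if perturbation is not None:
        known = set(dynamics.genes)
        for e in perturbation.effects:
            if e.gene not in known:
                raise ValueError(
                    f"perturbation affects gene {e.gene!r} absent from dynamics")
    rng = np.random.default_rng(seed)
    use_genes = list(genes) if genes is not None else dynamics.genes
    use_classes = (sort_classes(time_classes) if time_classes is not None
                   else dynamics.time_classes())
    tag = perturbation.target_gene if perturbation else "wt"
    embryos: list[SyntheticEmbryo] = []
    counter = 0
    for gene in use_genes:
        for tc in use_classes:
            if dynamics.cells_at(gene, tc).empty:
                continue
            for _ in range(n_per_class):
                counter += 1
                eff = (perturbation.draw_efficacy(rng)
                       if perturbation is not None else None)
                truth, pole_int = _realise_embryo_edges(
                    dynamics, gene, tc, rng, perturbation, eff)
                emb = SyntheticEmbryo(
                    embryo_id=f"{tag}_{gene}_{tc}_{counter:04d}",
                    gene=gene, time_class=tc, ground_truth=truth,
                    seed=seed, perturbed=(perturbation.target_gene
                                          if perturbation else None),
                    efficacy=eff, pole_intensity=pole_int,
                )
                if render in {"profile", "image"}:
                    domains = _truth_to_domains(gene, truth, edge_steepness)
                    prof, _ = make_profile(
                        domains, noise_sd=profile_noise_sd,
                        seed=int(rng.integers(0, 2**31 - 1)),
                        embryo_id=emb.embryo_id, gene=gene, time_class=tc)
                    emb.profile = prof
                    if render == "image":
                        rendered = make_embryo_image(
                            prof, seed=int(rng.integers(0, 2**31 - 1)))
                        emb.image, emb.mask = rendered.image, rendered.mask
                embryos.append(emb)
    return embryos


def _truth_to_domains(gene: str, truth: list[dict],
                      steepness: float) -> list[DomainSpec]:
    by_domain: dict[str, dict] = {}
    for row in truth:
        by_domain.setdefault(row["domain_id"], {})[row["edge"]] = row
    domains = []
    for domain_id, edges in by_domain.items():
        if any(r["absent"] for r in edges.values()):
            continue
        a = edges.get("anterior")
        p = edges.get("posterior")
        a_pos = a["position"] if a is not None else 0.0
        p_pos = p["position"] if p is not None else 100.0
        domains.append(DomainSpec(gene=gene, domain_id=domain_id,
                                  a_edge=min(a_pos, p_pos),
                                  p_edge=max(a_pos, p_pos),
                                  edge_steepness=steepness))
    return domains


# --------------------------------------------------------------------------
# cohort tables
# --------------------------------------------------------------------------

def cohort_truth_table(embryos: Iterable[SyntheticEmbryo]) -> pd.DataFrame:
    """Tidy ground-truth table: one row per realised edge."""
    rows = []
    for e in embryos:
        for t in e.ground_truth:
            rows.append({
                "embryo_id": e.embryo_id, "gene": e.gene,
                "time_class": e.time_class, "domain_id": t["domain_id"],
                "edge": t["edge"], "true_position": t["position"],
                "absent": t["absent"],
                "efficacy": e.efficacy if e.efficacy is not None else np.nan,
                "seed": e.seed if e.seed is not None else -1,
            })
    return pd.DataFrame(rows)


def cohort_boundary_table(embryos: Iterable[SyntheticEmbryo],
                          measurement_sd: float = 0.0,
                          seed: int | None = None) -> pd.DataFrame:
    """Boundary table as the measurement pipeline would emit it, taking
    realised ground-truth positions as the observations (optionally with
    extra measurement noise). Used to exercise aggregation and
    perturbation scoring without rendering images."""
    rng = np.random.default_rng(seed)
    rows = []
    for e in embryos:
        for t in e.ground_truth:
            pos = t["position"]
            if not t["absent"] and measurement_sd > 0:
                pos = float(np.clip(rng.normal(pos, measurement_sd), 0, 100))
            rows.append({
                "embryo_id": e.embryo_id, "gene": e.gene,
                "time_class": e.time_class, "domain_id": t["domain_id"],
                "edge": t["edge"],
                "position": pos if not t["absent"] else np.nan,
                "level_low": 0.0, "level_high": 1.0, "residual": 0.0,
                "flags": "absent" if t["absent"] else "",
                "pole_intensity": e.pole_intensity.get(t["domain_id"], 0.0),
            })
    return pd.DataFrame(rows)
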