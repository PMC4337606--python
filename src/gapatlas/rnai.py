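"""Scoring of RNAi knock-down cohorts against the wild-type atlas.

Each knock-down embryo's boundary set is compared to a wild-type envelope
(median +/- k x variability per atlas cell). Edges escaping the envelope
receive directional phenotype labels, embryos are counted into penetrance
tables, ordered into an allelic series by severity, and the per-pair
evidence is condensed into a signed, strength-annotated interaction
network.

The thresholds that operationalise "affected", "weak" and "strong"
(envelope multiplier, severity and penetrance cut-offs) are explicit
parameters with documented defaults; the underlying phenotype calls in the
literature are qualitative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import SpatioTemporalAtlas

__all__ = [
    "WtEnvelope",
    "PerturbationRecord",
    "InteractionEdge",
    "build_envelope",
    "classify_embryo",
    "classify_cohort",
    "penetrance",
    "allelic_series",
    "infer_network",
    "posterior_bias",
    "network_to_dot",
    "DEFAULT_REGULATOR_POSITIONS",
]

PHENOTYPE_LABELS = {
    "expanded_anterior", "expanded_posterior", "displaced_anterior",
    "displaced_posterior", "retraction_failure", "partial_retraction",
    "reduced", "absent", "unaffected",
}

#: Approximate A-P centres for regulators whose own expression is not part
#: of a trunk-gene atlas (terminal and maternal genes).
DEFAULT_REGULATOR_POSITIONS: dict[str, list[tuple[str, float]]] = {
    "tll": [("posterior", 95.0)],
    "hkb": [("posterior", 97.0), ("anterior", 4.0)],
    "bcd": [("anterior", 10.0)],
    "cad": [("posterior", 70.0)],
}


@dataclass
class WtEnvelope:
    """Wild-type tolerance band per atlas cell: centre +/- half_width,
    with half_width = k x variability."""

    cells: pd.DataFrame  # gene, domain_id, edge, time_class, centre, half_width, n, flags
    k: float
    pole_margin: float = 5.0  # %EL from the posterior pole counting as "at pole"

    def cell(self, gene, domain_id, edge, time_class) -> pd.Series:
        t = self.cells
        sel = t[(t["gene"] == gene) & (t["domain_id"] == domain_id)
                & (t["edge"] == edge) & (t["time_class"] == time_class)]
        if sel.empty:
            raise KeyError(
                f"no envelope cell for ({gene}, {domain_id}, {edge}, "
                f"{time_class})")
        return sel.iloc[0]

    def domains(self, gene: str, time_class: str) -> list[str]:
        t = self.cells
        sel = t[(t["gene"] == gene) & (t["time_class"] == time_class)]
        if sel.empty:
            raise KeyError(f"time class {time_class!r} absent from envelope "
                           f"for gene {gene!r}")
        return sorted(sel["domain_id"].unique())

    def domain_centres(self, gene: str, time_class: str) -> list[tuple[str, float]]:
        out = []
        for dom in self.domains(gene, time_class):
            t = self.cells
            sel = t[(t["gene"] == gene) & (t["domain_id"] == dom)
                    & (t["time_class"] == time_class)]
            out.append((dom, float(sel["centre"].mean())))
        return out


def build_envelope(atlas: SpatioTemporalAtlas, k: float = 2.0,
                   min_n: int = 3) -> WtEnvelope:
    """Envelope from a wild-type atlas: centre = median, half_width =
    k x variability. Cells with fewer than ``min_n`` embryos are kept but
    flagged as thin evidence."""
    cells = atlas.cells[atlas.cells["median"].notna()].copy()
    cells = cells.rename(columns={"median": "centre"})
    cells["half_width"] = k * cells["variability"]
    cells["flags"] = np.where(cells["n"] < min_n, "small_n", "")
    return WtEnvelope(
        cells=cells[["gene", "domain_id", "edge", "time_class", "centre",
                     "half_width", "n", "flags"]].reset_index(drop=True),
        k=k)


@dataclass
class PerturbationRecord:
    """Phenotype call for one RNAi-treated embryo against the wild type."""

    embryo_id: str
    knockdown_gene: str
    stained_gene: str
    time_class: str
    labels: tuple[str, ...]
    severity: float
    deviations: dict = field(default_factory=dict)
    efficacy: float | None = None

    @property
    def affected(self) -> bool:
        return self.labels != ("unaffected",)


def _row_lookup(rows: pd.DataFrame) -> dict[tuple[str, str], pd.Series]:
    return {(r["domain_id"], r["edge"]): r for _, r in rows.iterrows()}


def classify_embryo(embryo_rows: pd.DataFrame, envelope: WtEnvelope,
                    knockdown_gene: str,
                    efficacy: float | None = None) -> PerturbationRecord:
    """Classify one embryo's boundary set against the wild-type envelope.

    ``embryo_rows`` holds this embryo's boundary-table rows (one stained
    gene, one time class); a NaN position with an ``absent`` flag marks a
    missing domain. Labels follow the phenotype vocabulary: expansions and
    displacements are separated by whether the domain widened or moved as
    a whole; a domain persisting at the posterior pole past the wild-type
    retraction stage is a retraction failure (partial when residual pole
    intensity is intermediate).
    """
    if embryo_rows.empty:
        raise ValueError("embryo has no boundary rows")
    gene = embryo_rows["gene"].iloc[0]
    tc = embryo_rows["time_class"].iloc[0]
    embryo_id = embryo_rows["embryo_id"].iloc[0]
    wt_domains = envelope.domains(gene, tc)  # raises if tc missing
    obs = _row_lookup(embryo_rows)

    labels: list[str] = []
    severities: list[float] = [0.0]
    deviations: dict = {}

    for dom in wt_domains:
        dom_rows = {e: obs.get((dom, e)) for e in ("anterior", "posterior")}
        present = {e: r for e, r in dom_rows.items()
                   if r is not None and not pd.isna(r["position"])}
        wt_cells = {}
        for e in ("anterior", "posterior"):
            try:
                wt_cells[e] = envelope.cell(gene, dom, e, tc)
            except KeyError:
                pass
        if not wt_cells:
            continue
        if not present:
            labels.append("absent")
            centres = [c["centre"] for c in wt_cells.values()]
            severities.append(max(centres) - min(centres) if len(centres) > 1
                              else envelope.k)
            deviations[dom] = {"absent": True}
            continue

        devs = {}
        outside = {}
        for e, r in present.items():
            if e not in wt_cells:
                continue
            c = wt_cells[e]
            dev = float(r["position"] - c["centre"])
            devs[e] = dev
            outside[e] = abs(dev) > c["half_width"] + 1e-9
            severities.append(abs(dev))
        deviations[dom] = devs

        # retraction check at the posterior pole
        post = present.get("posterior")
        if post is not None and "posterior" in wt_cells:
            wt_post = wt_cells["posterior"]["centre"]
            at_pole = post["position"] >= 100.0 - envelope.pole_margin
            wt_retracted = wt_post < 100.0 - envelope.pole_margin
            if at_pole and wt_retracted:
                pole_int = post.get("pole_intensity", np.nan)
                if pd.isna(pole_int) or pole_int >= 0.5:
                    labels.append("retraction_failure")
                elif 0.25 <= pole_int < 0.5:
                    labels.append("partial_retraction")
                outside.pop("posterior", None)  # subsumed by retraction label

        out_edges = {e for e, o in outside.items() if o}
        if not out_edges:
            continue
        wt_width = None
        obs_width = None
        if len(wt_cells) == 2 and len(present) == 2:
            wt_width = (wt_cells["posterior"]["centre"]
                        - wt_cells["anterior"]["centre"])
            obs_width = (present["posterior"]["position"]
                         - present["anterior"]["position"])
        both_same_dir = (len(out_edges) == 2
                         and np.sign(devs["anterior"])
                         == np.sign(devs["posterior"]))
        if both_same_dir:
            direction = "anterior" if devs["anterior"] < 0 else "posterior"
            labels.append(f"displaced_{direction}")
            continue
        if (obs_width is not None and wt_width is not None
                and obs_width < wt_width and len(out_edges) == 2):
            labels.append("reduced")
            continue
        for e in sorted(out_edges):
            dev = devs[e]
            outward = (e == "anterior" and dev < 0) or \
                      (e == "posterior" and dev > 0)
            if outward:
                labels.append(f"expanded_{'anterior' if dev < 0 else 'posterior'}")
            elif obs_width is not None and wt_width is not None \
                    and obs_width < wt_width - 1e-9:
                labels.append("reduced")
            else:
                labels.append(f"displaced_{'anterior' if dev < 0 else 'posterior'}")

    final = tuple(sorted(set(labels))) if labels else ("unaffected",)
    return PerturbationRecord(
        embryo_id=embryo_id, knockdown_gene=knockdown_gene,
        stained_gene=gene, time_class=tc, labels=final,
        severity=float(max(severities)), deviations=deviations,
        efficacy=efficacy)


def classify_cohort(boundaries: pd.DataFrame, envelope: WtEnvelope,
                    knockdown_gene: str,
                    efficacies: dict[str, float] | None = None,
                    ) -> list[PerturbationRecord]:
    """Classify every embryo in an RNAi boundary table."""
    records = []
    for embryo_id, rows in boundaries.groupby("embryo_id", sort=True):
        eff = (efficacies or {}).get(embryo_id)
        records.append(classify_embryo(rows, envelope, knockdown_gene,
                                       efficacy=eff))
    return records


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def penetrance(records: list[PerturbationRecord]) -> pd.DataFrame:
    """Penetrance per (stained_gene, knockdown_gene): affected count, total
    and integer percentage (rounded half away from zero). An empty cell is
    reported with percent NaN."""
    rows = []
    df = pd.DataFrame([{
        "stained_gene": r.stained_gene, "knockdown_gene": r.knockdown_gene,
        "affected": r.affected} for r in records])
    if df.empty:
        return pd.DataFrame(columns=["stained_gene", "knockdown_gene",
                                     "n_affected", "n_total", "percent"])
    for (sg, kg), grp in df.groupby(["stained_gene", "knockdown_gene"],
                                    sort=True):
        n = len(grp)
        a = int(grp["affected"].sum())
        rows.append({"stained_gene": sg, "knockdown_gene": kg,
                     "n_affected": a, "n_total": n,
                     "percent": _round_half_away(100.0 * a / n) if n else np.nan})
    return pd.DataFrame(rows)


def penetrance_percent(n_affected: int, n_total: int) -> int:
    """Printed-style integer penetrance percentage for a single cell."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_affected <= n_total):
        raise ValueError("need 0 <= n_affected <= n_total")
    return _round_half_away(100.0 * n_affected / n_total)


def allelic_series(records: list[PerturbationRecord]) -> pd.DataFrame:
    """Order affected embryos of one stained gene by phenotype severity.

    Variable knock-down efficacy makes an RNAi cohort behave like an
    allelic series; when ground-truth efficacies are attached the Spearman
    rank correlation between efficacy and severity is reported in the
    result's ``attrs``. Requires at least 3 affected records.
    """
    affected = [r for r in records if r.affected]
    if not affected:
        return pd.DataFrame(columns=["embryo_id", "stained_gene",
                                     "severity", "efficacy"])
    genes = {r.stained_gene for r in affected}
    if len(genes) != 1:
        raise ValueError("allelic series needs records of one stained gene")
    if len(affected) < 3:
        raise ValueError("allelic series needs >= 3 affected records")
    df = pd.DataFrame([{
        "embryo_id": r.embryo_id, "stained_gene": r.stained_gene,
        "severity": r.severity, "efficacy": r.efficacy}
        for r in affected]).sort_values("severity").reset_index(drop=True)
    if df["efficacy"].notna().all() and df["severity"].nunique() > 1:
        rho = stats.spearmanr(df["efficacy"], df["severity"]).statistic
        df.attrs["efficacy_severity_spearman"] = float(rho)
    return df


# --------------------------------------------------------------------------
# network inference
# --------------------------------------------------------------------------

REPRESSION_LABELS = {"expanded_anterior", "expanded_posterior",
                     "retraction_failure", "partial_retraction"}
ACTIVATION_LABELS = {"reduced", "absent"}


@dataclass(frozen=True)
class InteractionEdge:
    """A regulator -> target interaction with sign and strength class."""

    regulator: str
    target: str
    sign: str                 # "repression" | "activation" | "none"
    strength: str             # "strong" | "weak" | "none"
    penetrance_pct: int
    n_affected: int
    n_total: int
    median_severity: float
    evidence: dict = field(default_factory=dict)


def _displacement_vote(record: PerturbationRecord,
                       regulator_centres: list[tuple[str, float]],
                       stained_centres: list[tuple[str, float]],
                       ) -> str | None:
    """Decide whether a displaced domain moved toward (repression released)
    or away from (activation lost) the regulator's nearest domain."""
    disp = [l for l in record.labels if l.startswith("displaced_")]
    if not disp or not regulator_centres or not stained_centres:
        return None
    direction = -1.0 if disp[0].endswith("anterior") else 1.0
    sc = float(np.mean([c for _, c in stained_centres]))
    reg = min((c for _, c in regulator_centres), key=lambda c: abs(c - sc))
    toward = np.sign(reg - sc)
    return "repression" if direction == toward else "activation"


def infer_network(records: list[PerturbationRecord],
                  envelope: WtEnvelope,
                  layout: dict[str, list[tuple[str, float]]] | None = None,
                  min_penetrance: float = 25.0,
                  strong_penetrance: float = 50.0,
                  strong_severity: float = 5.0,
                  weak_severity: float = 2.0,
                  reference_class: str = "T4",
                  ) -> list[InteractionEdge]:
    """Condense per-embryo phenotype calls into a signed interaction list.

    Per (knock-down -> stained) pair with penetrance >= ``min_penetrance``
    percent: the sign is repression when the dominant evidence is
    expansion / displacement toward the regulator's domain / retraction
    failure, activation when it is reduction or absence. Strength is
    "strong" for median severity >= ``strong_severity`` %EL with
    penetrance >= ``strong_penetrance``; "weak" for severity in
    [``weak_severity``, ``strong_severity``) or penetrance in
    [``min_penetrance``, ``strong_penetrance``); otherwise "none".
    """
    layout = dict(DEFAULT_REGULATOR_POSITIONS | (layout or {}))
    by_pair: dict[tuple[str, str], list[PerturbationRecord]] = {}
    for r in records:
        by_pair.setdefault((r.knockdown_gene, r.stained_gene), []).append(r)

    edges: list[InteractionEdge] = []
    for (kg, sg), recs in sorted(by_pair.items()):
        n = len(recs)
        affected = [r for r in recs if r.affected]
        if n == 0:
            continue
        pct = _round_half_away(100.0 * len(affected) / n)
        if pct < min_penetrance:
            continue
        try:
            stained_centres = envelope.domain_centres(sg, reference_class)
        except KeyError:
            stained_centres = []
        reg_centres = layout.get(kg)
        if reg_centres is None:
            try:
                reg_centres = envelope.domain_centres(kg, reference_class)
            except KeyError:
                reg_centres = []

        rep_votes = act_votes = 0
        label_counts: dict[str, int] = {}
        for r in affected:
            for l in r.labels:
                label_counts[l] = label_counts.get(l, 0) + 1
            if set(r.labels) & REPRESSION_LABELS:
                rep_votes += 1
            if set(r.labels) & ACTIVATION_LABELS:
                act_votes += 1
            vote = _displacement_vote(r, reg_centres, stained_centres)
            if vote == "repression":
                rep_votes += 1
            elif vote == "activation":
                act_votes += 1
        sign = ("repression" if rep_votes >= act_votes and rep_votes > 0
                else "activation" if act_votes > 0 else "none")
        med_sev = float(np.median([r.severity for r in affected]))
        if med_sev >= strong_severity and pct >= strong_penetrance:
            strength = "strong"
        elif med_sev >= weak_severity or pct < strong_penetrance:
            strength = "weak"
        else:
            strength = "none"
        edges.append(InteractionEdge(
            regulator=kg, target=sg, sign=sign, strength=strength,
            penetrance_pct=pct, n_affected=len(affected), n_total=n,
            median_severity=med_sev,
            evidence={"labels": label_counts, "repression_votes": rep_votes,
                      "activation_votes": act_votes}))
    return edges


#: Overlapping neighbour pairs (anterior gene, posterior gene) entering the
#: posterior-bias score.
OVERLAP_PAIRS = [("Kr", "kni"), ("kni", "gt"), ("gt", "hb")]

_STRENGTH_SCORE = {"strong": 2.0, "weak": 1.0, "none": 0.0}


def posterior_bias(edges: list[InteractionEdge],
                   pairs: list[tuple[str, str]] | None = None) -> float:
    """Mean repression-strength score of posterior-to-anterior neighbour
    interactions minus anterior-to-posterior ones, over the overlapping
    domain pairs. Positive values mean repression is biased toward acting
    from posterior onto anterior neighbours."""
    pairs = pairs if pairs is not None else OVERLAP_PAIRS
    index = {(e.regulator, e.target): e for e in edges}

    def score(reg, tgt):
        e = index.get((reg, tgt))
        if e is None or e.sign != "repression":
            return 0.0
        return _STRENGTH_SCORE[e.strength]

    p2a = [score(post, ant) for ant, post in pairs]
    a2p = [score(ant, post) for ant, post in pairs]
    return float(np.mean(p2a) - np.mean(a2p))


def network_to_dot(edges: list[InteractionEdge]) -> str:
    """GraphViz DOT export: T-bar arrowheads for repression, line width by
    strength."""
    width = {"strong": 3.0, "weak": 1.5, "none": 0.5}
    lines = ["digraph gap_network {", "  rankdir=LR;"]
    for e in edges:
        arrow = "tee" if e.sign == "repression" else "normal"
        lines.append(
            f'  "{e.regulator}" -> "{e.target}" '
            f'[arrowhead={arrow}, penwidth={width[e.strength]}, '
            f'label="{e.penetrance_pct}%"];')
    lines.append("}")
    return "\n".join(lines)


def network_to_digraph(edges: list[InteractionEdge]):
    """The edge list as a networkx DiGraph with edge attributes."""
    import networkx as nx

    g = nx.DiGraph()
    for e in edges:
        g.add_edge(e.regulator, e.target, sign=e.sign, strength=e.strength,
                   penetrance_pct=e.penetrance_pct,
                   median_severity=e.median_severity)
    return g
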