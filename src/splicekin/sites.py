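"""Position-weight-matrix and maximum-entropy splice-site models.

Both scorers operate on fixed-width site windows — donor 9-mers (3 exonic +
6 intronic bases) and acceptor 23-mers (20 intronic + 3 exonic), the
MaxEntScan window convention — and report log2 likelihood ratios against a
background base composition. Scores carry no threshold; they are only
meaningful when comparing related sites of the same type under the same
model.

The maximum-entropy model is the least-committed distribution matching the
training set's positional marginals (order 1) and, optionally, its
adjacent-pair marginals (order "2-adjacent"). It is fitted by generalized
iterative scaling; because the constraints form a chain, model expectations
and the partition function are computed exactly by forward–backward
recursions, so the full 4^W outcome space is never enumerated. With order-1
constraints only, the solution factorizes over positions and the scores
coincide with the PWM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import GeneModel
from .splicing import SpliceEvent

__all__ = [
    "SiteModel",
    "SiteComparison",
    "train_pwm",
    "train_maxent",
    "score_window",
    "score_event_sites",
    "DONOR_WIDTH",
    "ACCEPTOR_WIDTH",
]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
DONOR_WIDTH = 9       # 3 exonic + 6 intronic
ACCEPTOR_WIDTH = 23   # 20 intronic + 3 exonic
DONOR_EXONIC = 3
ACCEPTOR_INTRONIC = 20
SCORE_FLOOR = -20.0   # bits per position, guards log(0) without pseudocount


def _encode(windows) -> np.ndarray:
    arr = np.array([[BASE_INDEX[b] for b in w] for w in windows], dtype=int)
    return arr


@dataclass
class SiteModel:
    """A trained splice-site scorer.

    ``kind`` is 'pwm' or 'maxent'; ``site_type`` is 'donor' or 'acceptor'.
    For a PWM, ``freqs`` holds per-position base frequencies (rows sum to 1).
    For a max-ent model, ``node_pot``/``edge_pot`` hold log-potentials of the
    chain-structured exponential family and ``log_z`` its normalizer.
    """

    kind: str
    site_type: str
    width: int
    background: np.ndarray
    freqs: np.ndarray | None = None
    node_pot: np.ndarray | None = None       # (W, 4) log potentials
    edge_pot: np.ndarray | None = None       # (W-1, 4, 4) log potentials
    log_z: float = 0.0

    def log_prob(self, window: str) -> float:
        """log2 probability of a window under the site model."""
        if len(window) != self.width:
            raise ValueError(f"window width {len(window)} != model width {self.width}")
        idx = [BASE_INDEX[b] for b in window]
        if self.kind == "pwm":
            with np.errstate(divide="ignore"):
                logs = np.log2(self.freqs[np.arange(self.width), idx])
            return float(np.maximum(logs, SCORE_FLOOR).sum())
        lp = sum(self.node_pot[i, idx[i]] for i in range(self.width))
        if self.edge_pot is not None:
            lp += sum(
                self.edge_pot[i, idx[i], idx[i + 1]] for i in range(self.width - 1)
            )
        return float((lp - self.log_z) / np.log(2))

    def score(self, window: str) -> float:
        """log2 likelihood ratio vs the background composition."""
        idx = [BASE_INDEX[b] for b in window]
        with np.errstate(divide="ignore"):
            bg = np.log2(self.background[idx]).sum()
        return self.log_prob(window) - float(bg)


def _marginals(arr: np.ndarray, pseudocount: float) -> np.ndarray:
    n, w = arr.shape
    m = np.zeros((w, 4))
    for i in range(w):
        m[i] = np.bincount(arr[:, i], minlength=4)
    m += pseudocount
    return m / m.sum(axis=1, keepdims=True)


def _pair_marginals(arr: np.ndarray, pseudocount: float) -> np.ndarray:
    n, w = arr.shape
    p = np.zeros((w - 1, 4, 4))
    for i in range(w - 1):
        np.add.at(p[i], (arr[:, i], arr[:, i + 1]), 1.0)
    p += pseudocount
    return p / p.sum(axis=(1, 2), keepdims=True)


def train_pwm(
    windows,
    site_type: str,
    background: np.ndarray | None = None,
    pseudocount: float = 0.5,
) -> SiteModel:
    """Per-position frequency model; score(w) = Σ log2 f_i(w_i)/bg(w_i)."""
    widths = {len(w) for w in windows}
    if len(widths) != 1:
        raise ValueError(f"training windows of mixed widths {sorted(widths)}")
    if len(windows) < 10:
        raise ValueError("need at least 10 training sites")
    arr = _encode(windows)
    freqs = _marginals(arr, pseudocount)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return SiteModel(
        kind="pwm",
        site_type=site_type,
        width=arr.shape[1],
        background=bg,
        freqs=freqs,
    )


def _chain_marginals(node_pot, edge_pot):
    """Exact node and edge marginals of a chain MRF (forward-backward in
    log space is unnecessary: potentials stay small, use scaled messages)."""
    w = node_pot.shape[0]
    phi = np.exp(node_pot)
    psi = np.exp(edge_pot) if edge_pot is not None else np.ones((w - 1, 4, 4))
    fwd = np.zeros((w, 4))
    scale = np.zeros(w)
    fwd[0] = phi[0]
    scale[0] = fwd[0].sum()
    fwd[0] /= scale[0]
    for i in range(1, w):
        fwd[i] = phi[i] * (fwd[i - 1] @ psi[i - 1])
        scale[i] = fwd[i].sum()
        fwd[i] /= scale[i]
    bwd = np.ones((w, 4))
    for i in range(w - 2, -1, -1):
        bwd[i] = psi[i] @ (phi[i + 1] * bwd[i + 1])
        bwd[i] /= bwd[i].sum()
    node_m = fwd * bwd
    node_m /= node_m.sum(axis=1, keepdims=True)
    edge_m = np.zeros((w - 1, 4, 4))
    for i in range(w - 1):
        m = np.outer(fwd[i], phi[i + 1] * bwd[i + 1]) * psi[i]
        edge_m[i] = m / m.sum()
    log_z = float(np.log(scale).sum())
    return node_m, edge_m, log_z


def train_maxent(
    windows,
    site_type: str,
    constraint_order: str = "1",
    background: np.ndarray | None = None,
    pseudocount: float = 0.5,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> SiteModel:
    """Fit a maximum-entropy site model by generalized iterative scaling.

    ``constraint_order`` '1' matches positional marginals only (equivalent to
    the PWM); '2-adjacent' additionally matches adjacent-pair marginals.
    Raises on non-convergence, carrying the final marginal discrepancy.
    """
    if constraint_order not in ("1", "2-adjacent"):
        raise ValueError(f"unknown constraint order {constraint_order!r}")
    widths = {len(w) for w in windows}
    if len(widths) != 1:
        raise ValueError(f"training windows of mixed widths {sorted(widths)}")
    if len(windows) < 10:
        raise ValueError("need at least 10 training sites")
    arr = _encode(windows)
    w = arr.shape[1]
    use_pairs = constraint_order == "2-adjacent" and w > 1
    if use_pairs:
        target_edge = _pair_marginals(arr, pseudocount)
        # node targets derived from the pair marginals so the constraint set
        # is self-consistent under the shared pseudocount
        target_node = np.empty((w, 4))
        target_node[0] = target_edge[0].sum(axis=1)
        for i in range(1, w):
            target_node[i] = target_edge[i - 1].sum(axis=0)
    else:
        target_edge = None
        target_node = _marginals(arr, pseudocount)

    # start at the chain closed form (first-order Markov chain), which already
    # satisfies consistent chain constraints; GIS then only polishes
    node_pot = np.log(target_node)
    if use_pairs:
        edge_pot = np.log(
            target_edge
            / (target_node[:-1, :, None] * target_node[1:, None, :])
        )
    else:
        edge_pot = None
    C = w + (w - 1 if use_pairs else 0)  # features active per outcome

    disc = np.inf
    for _ in range(max_iter):
        node_m, edge_m, _ = _chain_marginals(node_pot, edge_pot)
        disc = float(np.abs(node_m - target_node).max())
        if use_pairs:
            disc = max(disc, float(np.abs(edge_m - target_edge).max()))
        if disc < tol:
            break
        node_pot += np.log(target_node / np.maximum(node_m, 1e-300)) / C
        if use_pairs:
            edge_pot += np.log(target_edge / np.maximum(edge_m, 1e-300)) / C
    else:
        raise RuntimeError(
            f"maxent GIS did not converge in {max_iter} iterations "
            f"(max marginal discrepancy {disc:.3g})"
        )
    _, _, log_z = _chain_marginals(node_pot, edge_pot)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return SiteModel(
        kind="maxent",
        site_type=site_type,
        width=w,
        background=bg,
        node_pot=node_pot,
        edge_pot=edge_pot,
        log_z=log_z,
    )


def score_window(model: SiteModel, window: str) -> float:
    return model.score(window)


# ---------------------------------------------------------------------------
# Event-site comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteComparison:
    """Actual vs alternative site of one event under one model.

    Scores have no absolute threshold; only the within-row comparison is
    meaningful. ``dominant`` is 'actual', 'alternative' or 'tie'.
    """

    event_key: tuple
    site_type: str
    model_kind: str
    actual_pos: int
    alternative_pos: int
    actual_score: float
    alternative_score: float

    @property
    def dominant(self) -> str:
        if np.isclose(self.actual_score, self.alternative_score):
            return "tie"
        return "actual" if self.actual_score > self.alternative_score else "alternative"


def donor_window(genomic: str, donor_pos: int) -> str:
    """9-mer around a donor site (3 exonic + 6 intronic); ``donor_pos`` is the
    genomic offset of the first intronic base."""
    s, e = donor_pos - DONOR_EXONIC, donor_pos + (DONOR_WIDTH - DONOR_EXONIC)
    if s < 0 or e > len(genomic):
        raise ValueError("donor window extends past sequence end")
    return genomic[s:e]


def acceptor_window(genomic: str, acceptor_pos: int) -> str:
    """23-mer around an acceptor site (20 intronic + 3 exonic);
    ``acceptor_pos`` is the genomic offset of the first exonic base."""
    s, e = acceptor_pos - ACCEPTOR_INTRONIC, acceptor_pos + (ACCEPTOR_WIDTH - ACCEPTOR_INTRONIC)
    if s < 0 or e > len(genomic):
        raise ValueError("acceptor window extends past sequence end")
    return genomic[s:e]


def score_event_sites(
    event: SpliceEvent, model: GeneModel, site_models: dict
) -> list[SiteComparison]:
    """Score actual vs alternative splice sites of an alternative-site event.

    ``site_models`` maps (kind, site_type) -> SiteModel, e.g.
    ``{("pwm", "donor"): ..., ("maxent", "acceptor"): ...}``. Events that use
    only annotated sites (pure exon skipping) yield no comparisons; the
    paired exon-internal class yields one donor pair and one acceptor pair,
    compared against the enclosing exon's own sites.
    """
    g = model.genomic_seq
    gs, ge = event.gap
    pairs: list[tuple[str, int, int]] = []  # (site_type, actual_pos, alt_pos)
    if event.mechanism == "alt5ss":
        i = event.affected[0]
        pairs.append(("donor", model.exons[i][1], gs))
    elif event.mechanism == "alt3ss":
        j = event.affected[0]
        pairs.append(("acceptor", model.exons[j][0], ge))
    elif event.mechanism == "alt3ss_alt5ss":
        ex = event.affected[0]
        if ex + 1 < model.n_exons:
            pairs.append(("donor", model.exons[ex][1], gs))
        if ex > 0:
            pairs.append(("acceptor", model.exons[ex][0], ge))
    elif event.mechanism == "partial_intron_retention":
        i = event.affected[0]
        if event.shift_nt is not None and event.shift_nt > 0:
            pairs.append(("donor", model.exons[i][1], gs))
        else:
            pairs.append(("acceptor", model.exons[i + 1][0], ge))
    out = []
    for site_type, actual, alt in pairs:
        extract = donor_window if site_type == "donor" else acceptor_window
        for (kind, stype), sm in sorted(site_models.items()):
            if stype != site_type:
                continue
            out.append(
                SiteComparison(
                    event_key=event.key,
                    site_type=site_type,
                    model_kind=kind,
                    actual_pos=actual,
                    alternative_pos=alt,
                    actual_score=sm.score(extract(g, actual)),
                    alternative_score=sm.score(extract(g, alt)),
                )
            )
    return out
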