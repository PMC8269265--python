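"""SteadyCom numerical core: fixed-μ LP, bisection, FVA, medoid, L1 polish.

The community steady state imposes one shared growth rate μ on all members.
With per-member abundances X_k (gDW, normalised to ΣX = 1) and aggregate
fluxes V (mmol·h⁻¹ per gDW of community), the fixed-μ LP is

    maximize   Σ_k X_k
    subject to S·V = 0                      (member + lumen mass balance)
               lb_j·X_k ≤ V_j ≤ ub_j·X_k   (member reactions, abundance-scaled)
               V[biomass_k] = μ·X_k
               lb_m ≤ V[EX_m] ≤ ub_m       (community exchanges, medium-fixed)
               X_k ≥ 0.

μmax is the largest μ at which max ΣX ≥ 1 (the optimum scales down onto
ΣX = 1), located by bisection.  The canonical solution then follows the
chain FVA → medoid biomass floors → constrained re-solve → L1 flux
minimization, which removes futile cycles and resolves degenerate
abundance splits deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .community import CommunityModel

logger = logging.getLogger(__name__)

#: solver feasibility tolerance (primal and dual)
FEAS_TOL = 1e-8
#: absolute bisection tolerance on μ (h⁻¹)
MU_TOL = 1e-7
#: μ probe below which a community counts as non-growing; must sit well
#: above FEAS_TOL or zero-growth models leak through the tolerance
MU_PROBE = 1e-6
#: weight of the lexicographic abundance tie-break inside the L1 polish
LEX_EPS = 1e-9
#: cap on raw abundance variables; keeps the max-ΣX LP bounded at tiny μ
#: (the optimum is rescaled onto ΣX = 1, so the cap never binds a result)
X_MAX = 1e6

_HIGHS_OPTS = {
    "primal_feasibility_tolerance": FEAS_TOL,
    "dual_feasibility_tolerance": FEAS_TOL,
    "presolve": True,
}


class SteadyComError(RuntimeError):
    pass


@dataclass
class SteadyComSolution:
    """Community growth rate, abundances and aggregate fluxes."""

    community: CommunityModel
    medium: str
    mu: float
    X: Dict[str, float]
    V: Dict[str, float]
    status: str  # optimal | no_growth
    notes: Dict[str, object] = field(default_factory=dict)

    @property
    def members(self) -> List[str]:
        return self.community.members

    @property
    def growth_rates(self) -> Dict[str, float]:
        """Biomass formation rate μ·X_k per member (gDW·h⁻¹)."""
        return {k: self.mu * self.X[k] for k in self.members}

    def species_lumen_flux(self, member: str) -> Dict[str, float]:
        """Net flux of each lumen metabolite into the lumen from ``member``.

        Positive = secretion into the lumen, negative = uptake.
        """
        out: Dict[str, float] = {}
        for r in self.community.species_exchanges(member):
            coef = r.stoich[r.lumen_metabolite]
            out[r.lumen_metabolite] = (out.get(r.lumen_metabolite, 0.0)
                                       + coef * self.V[r.id])
        return out

    def community_secretion(self) -> Dict[str, float]:
        """Community-exchange flux per lumen metabolite (positive = secreted
        to the environment, negative = uptake from the environment)."""
        return {lum: self.V[r.id]
                for lum, r in self.community.community_exchanges.items()}

    def lumen_residuals(self) -> Dict[str, float]:
        """Σ species exchange + community exchange per lumen metabolite.

        Community exchange counts negatively into the lumen when secreting,
        so a closed lumen gives residual 0.
        """
        res = {lum: 0.0 for lum in self.community.lumen_metabolites}
        for r in self.community.reactions:
            if r.lumen_metabolite is not None:
                res[r.lumen_metabolite] += (r.stoich[r.lumen_metabolite]
                                            * self.V[r.id])
        return res


@dataclass
class FVAReport:
    members: List[str]
    ranges: Dict[str, Optional[Tuple[float, float]]]
    growth_vectors: List[np.ndarray]   # μ·X per solve, member order
    mu: float


@dataclass
class MedoidConstraint:
    """Per-member lower bounds on the biomass value (gDW·h⁻¹ by default)."""

    bounds: Dict[str, float]
    mode: str = "growth_rate"   # or "abundance"
    #: μ at which the medoid vector is known feasible (the FVA μ); seeds
    #: the constrained bisection, since with growth-rate floors small μ is
    #: the infeasible side
    mu_seed: Optional[float] = None

    def __post_init__(self):
        if self.mode not in ("growth_rate", "abundance"):
            raise ValueError(f"unknown medoid mode {self.mode!r}")
        if any(v < 0 for v in self.bounds.values()):
            raise ValueError("medoid bounds must be non-negative")


class SteadyComProblem:
    """LP assembly for one community; reused across μ values."""

    def __init__(self, community: CommunityModel):
        self.community = community
        self.K = len(community.members)
        self.R = len(community.reactions)
        self.member_index = {k: i for i, k in enumerate(community.members)}
        self.rxn_index = {r.id: j for j, r in enumerate(community.reactions)}
        self.met_index = {m: i for i, m in
                          enumerate(community.metabolite_ids)}
        n = self.K + self.R

        rows, cols, vals = [], [], []
        for j, r in enumerate(community.reactions):
            for m, c in r.stoich.items():
                rows.append(self.met_index[m])
                cols.append(self.K + j)
                vals.append(c)
        self.S = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.met_index), n))

        # abundance-coupled bounds for member-owned reactions
        ub_rows, lb_rows = [], []
        for j, r in enumerate(community.reactions):
            if r.member is None:
                continue
            if not np.isfinite(r.lower_bound) or not np.isfinite(
                    r.upper_bound):
                raise SteadyComError(
                    f"reaction {r.id}: abundance-coupled bounds must be "
                    f"finite")
            k = self.member_index[r.member]
            row = np.zeros(n)
            row[self.K + j] = 1.0
            row[k] = -r.upper_bound
            ub_rows.append(row)
            row = np.zeros(n)
            row[self.K + j] = -1.0
            row[k] = r.lower_bound
            lb_rows.append(row)
        self.A_couple = sparse.csr_matrix(np.array(ub_rows + lb_rows)) \
            if ub_rows else sparse.csr_matrix((0, n))

        self.biomass_cols = {
            k: self.K + self.rxn_index[community.biomass_reaction_of[k]]
            for k in community.members}
        self.exchange_bounds = {
            self.K + self.rxn_index[r.id]: (r.lower_bound, r.upper_bound)
            for r in community.reactions if r.is_community_exchange}

    # ------------------------------------------------------------------
    def solve(self, mu: float, *,
              objective: object = "max_total",
              fix_total: Optional[float] = None,
              fixed_X: Optional[Dict[str, float]] = None,
              biomass_floor: Optional[Dict[str, float]] = None,
              abundance_floor: Optional[Dict[str, float]] = None,
              lex_eps: float = 0.0) -> Dict[str, object]:
        """Solve one LP at fixed μ.

        ``objective`` is ``"max_total"`` (max ΣX), ``("min"|"max", rxn_id)``
        for FVA, or ``"l1"`` (min Σ|V|, optionally with the lexicographic
        abundance tie-break weighted by ``lex_eps``).
        """
        K, R = self.K, self.R
        l1 = objective == "l1"
        n = K + R + (R if l1 else 0)

        def widen(mat):
            if not l1 or mat.shape[0] == 0:
                return mat if mat.shape[1] == n else sparse.hstack(
                    [mat, sparse.csr_matrix((mat.shape[0], n - mat.shape[1]))],
                    format="csr")
            return sparse.hstack(
                [mat, sparse.csr_matrix((mat.shape[0], R))], format="csr")

        eq_blocks = [widen(self.S)]
        b_eq = [np.zeros(self.S.shape[0])]
        # biomass coupling V_bio_k = mu X_k
        rows, cols, vals = [], [], []
        for i, k in enumerate(self.community.members):
            rows += [i, i]
            cols += [self.biomass_cols[k], self.member_index[k]]
            vals += [1.0, -mu]
        eq_blocks.append(sparse.csr_matrix((vals, (rows, cols)),
                                           shape=(K, n)))
        b_eq.append(np.zeros(K))
        if fix_total is not None:
            row = np.zeros(n)
            row[:K] = 1.0
            eq_blocks.append(sparse.csr_matrix(row))
            b_eq.append(np.array([fix_total]))

        ub_blocks = [widen(self.A_couple)]
        b_ub = [np.zeros(self.A_couple.shape[0])]
        if biomass_floor:
            for k, floor in biomass_floor.items():
                row = np.zeros(n)
                row[self.biomass_cols[k]] = -1.0
                ub_blocks.append(sparse.csr_matrix(row))
                b_ub.append(np.array([-floor]))
        if l1:
            # t_j ≥ ±V_j
            rows, cols, vals = [], [], []
            for j in range(R):
                rows += [2 * j, 2 * j, 2 * j + 1, 2 * j + 1]
                cols += [K + j, K + R + j, K + j, K + R + j]
                vals += [1.0, -1.0, -1.0, -1.0]
            ub_blocks.append(sparse.csr_matrix((vals, (rows, cols)),
                                               shape=(2 * R, n)))
            b_ub.append(np.zeros(2 * R))

        bounds: List[Tuple[Optional[float], Optional[float]]] = []
        for i, k in enumerate(self.community.members):
            lo = 0.0
            if abundance_floor and k in abundance_floor:
                lo = abundance_floor[k]
            if fixed_X is not None:
                bounds.append((fixed_X[k], fixed_X[k]))
            else:
                bounds.append((lo, X_MAX))
        for j in range(R):
            col = K + j
            if col in self.exchange_bounds:
                bounds.append(self.exchange_bounds[col])
            else:
                bounds.append((None, None))
        if l1:
            bounds.extend([(0.0, None)] * R)

        c = np.zeros(n)
        if objective == "max_total":
            c[:K] = -1.0
        elif l1:
            c[K + R:] = 1.0
            if lex_eps:
                for rank, k in enumerate(self.community.members):
                    c[self.member_index[k]] = lex_eps * (rank + 1)
        else:
            sense, rxn_id = objective
            j = self.rxn_index[rxn_id]
            c[K + j] = 1.0 if sense == "min" else -1.0

        res = linprog(c, A_ub=sparse.vstack(ub_blocks, format="csr"),
                      b_ub=np.concatenate(b_ub),
                      A_eq=sparse.vstack(eq_blocks, format="csr"),
                      b_eq=np.concatenate(b_eq),
                      bounds=bounds, method="highs", options=_HIGHS_OPTS)
        if res.status == 3:
            raise SteadyComError(
                f"community {self.community.id}: LP unbounded at mu={mu} — "
                f"model is missing secretion caps")
        if res.status != 0:
            return {"status": "infeasible"}
        X = np.array(res.x[:K])
        V = np.array(res.x[K:K + R])
        return {"status": "optimal", "X": X, "V": V,
                "total": float(X.sum()), "objective": float(res.fun)}

    def as_solution(self, mu: float, X: np.ndarray, V: np.ndarray,
                    status: str = "optimal",
                    notes: Optional[dict] = None) -> SteadyComSolution:
        return SteadyComSolution(
            community=self.community,
            medium=self.community.medium_name or "unspecified",
            mu=mu,
            X={k: float(X[i]) for i, k in
               enumerate(self.community.members)},
            V={r.id: float(V[j]) for j, r in
               enumerate(self.community.reactions)},
            status=status, notes=dict(notes or {}))


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def steadycom_lp(community: CommunityModel, mu: float,
                 problem: Optional[SteadyComProblem] = None) -> Dict[str, object]:
    """Max-ΣX LP at fixed μ; X (and V) rescaled onto ΣX = 1 when ΣX ≥ 1."""
    if mu < 0:
        raise ValueError("mu must be non-negative")
    prob = problem or SteadyComProblem(community)
    res = prob.solve(mu, objective="max_total")
    if res["status"] != "optimal":
        if mu == 0:
            raise SteadyComError(
                f"community {community.id}: infeasible at mu=0 — "
                f"structurally broken model")
        return {"feasible": False, "X": None, "V": None, "total": 0.0}
    total = res["total"]
    X, V = res["X"], res["V"]
    if total >= 1.0:
        X, V = X / total, V / total
    return {"feasible": total >= 1.0 - FEAS_TOL,
            "X": {k: float(X[i]) for i, k in enumerate(community.members)},
            "V": {r.id: float(V[j]) for j, r in
                  enumerate(community.reactions)},
            "total": total}


def _zero_solution(prob: SteadyComProblem, notes=None) -> SteadyComSolution:
    return prob.as_solution(0.0, np.zeros(prob.K), np.zeros(prob.R),
                            status="no_growth", notes=notes)


def _bisect_max_growth(prob: SteadyComProblem, mu_tol: float,
                       solve_kwargs: dict,
                       probe: float = MU_PROBE) -> Optional[float]:
    """Largest μ ≥ probe with max ΣX ≥ 1, or None when infeasible at the
    probe (no growth, or floors unattainable)."""

    def feasible(mu: float) -> bool:
        res = prob.solve(mu, objective="max_total", **solve_kwargs)
        return res["status"] == "optimal" and res["total"] >= 1.0 - FEAS_TOL

    if not feasible(probe):
        return None
    lo, hi = probe, max(1.0, 2.0 * probe)
    expansions = 0
    while feasible(hi):
        lo, hi = hi, hi * 2.0
        expansions += 1
        if expansions > 60:
            raise SteadyComError(
                f"community {prob.community.id}: growth rate bracket "
                f"expansion did not terminate (missing caps?)")
    while hi - lo > mu_tol:
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            lo = mid
        else:
            hi = mid
    return lo


def _finalize(prob: SteadyComProblem, mu: float, solve_kwargs: dict,
              notes: dict) -> SteadyComSolution:
    """Canonical solve at μ: ΣX = 1, L1-minimal flux, lexicographic ties."""
    res = prob.solve(mu, objective="l1", fix_total=1.0, lex_eps=LEX_EPS,
                     **solve_kwargs)
    if res["status"] != "optimal":
        # numerically marginal at the bisection point: fall back to the
        # rescaled max-ΣX optimum
        res = prob.solve(mu, objective="max_total", **solve_kwargs)
        if res["status"] != "optimal" or res["total"] <= 0:
            return _zero_solution(prob, notes)
        scale = max(res["total"], 1.0)
        return prob.as_solution(mu, res["X"] / scale, res["V"] / scale,
                                notes={**notes, "polish": "rescaled"})
    return prob.as_solution(mu, res["X"], res["V"], notes=notes)


def steadycom_max_growth(community: CommunityModel,
                         mu_tol: float = MU_TOL,
                         problem: Optional[SteadyComProblem] = None
                         ) -> SteadyComSolution:
    """Maximum community growth rate via bisection on LP feasibility."""
    prob = problem or SteadyComProblem(community)
    mu = _bisect_max_growth(prob, mu_tol, {})
    if mu is None:
        return _zero_solution(prob)
    return _finalize(prob, mu, {}, {"mu_tol": mu_tol})


def steadycom_fva(community: CommunityModel,
                  solution: Optional[SteadyComSolution] = None,
                  fraction: float = 0.9999,
                  reactions: Optional[Sequence[str]] = None,
                  problem: Optional[SteadyComProblem] = None) -> FVAReport:
    """Flux ranges at μ = fraction·μmax with ΣX = 1.

    Every solve also records the member growth-rate vector μ·X, the raw
    material for the medoid biomass constraint (two vectors per scanned
    reaction).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    prob = problem or SteadyComProblem(community)
    if solution is None:
        solution = steadycom_max_growth(community, problem=prob)
    if solution.mu <= 0:
        raise SteadyComError(
            f"community {community.id}: FVA requires positive growth")
    mu_f = fraction * solution.mu
    scan = list(reactions) if reactions is not None else \
        [r.id for r in community.reactions]
    ranges: Dict[str, Optional[Tuple[float, float]]] = {}
    vectors: List[np.ndarray] = []
    for rxn_id in scan:
        lohi = []
        ok = True
        for sense in ("min", "max"):
            res = prob.solve(mu_f, objective=(sense, rxn_id), fix_total=1.0)
            if res["status"] != "optimal":
                ok = False
                break
            j = prob.rxn_index[rxn_id]
            lohi.append(float(res["V"][j]))
            vectors.append(mu_f * res["X"])
        if ok:
            ranges[rxn_id] = (lohi[0], lohi[1])
        else:
            logger.warning("FVA: solver failure on %s, flagged", rxn_id)
            ranges[rxn_id] = None
    return FVAReport(members=list(community.members), ranges=ranges,
                     growth_vectors=vectors, mu=mu_f)


def compute_medoid(report: FVAReport,
                   mode: str = "growth_rate") -> MedoidConstraint:
    """Medoid of the recorded growth-rate vectors as per-member floors.

    The medoid is the recorded K-vector minimizing the sum of Euclidean
    distances to all recorded vectors; ties break on first occurrence.
    With ``mode="growth_rate"`` its components floor the biomass formation
    rate μ·X_k; with ``mode="abundance"`` they floor X_k (divided by μ).
    """
    if not report.growth_vectors:
        raise ValueError("empty FVA report: no growth-rate vectors")
    M = np.vstack(report.growth_vectors)
    diff = M[:, None, :] - M[None, :, :]
    dist_sums = np.sqrt((diff ** 2).sum(axis=2)).sum(axis=1)
    medoid = M[int(np.argmin(dist_sums))]
    if mode == "abundance":
        bounds = {k: float(medoid[i]) / report.mu
                  for i, k in enumerate(report.members)}
    else:
        bounds = {k: float(medoid[i]) for i, k in enumerate(report.members)}
    return MedoidConstraint(bounds=bounds, mode=mode, mu_seed=report.mu)


def solve_constrained(community: CommunityModel,
                      medoid: MedoidConstraint,
                      mu_tol: float = MU_TOL,
                      relax_factor: float = 0.99,
                      max_relaxations: int = 100,
                      problem: Optional[SteadyComProblem] = None
                      ) -> SteadyComSolution:
    """Re-run max growth with the medoid floors; relax geometrically if the
    floors are infeasible (×``relax_factor`` per iteration, logged)."""
    prob = problem or SteadyComProblem(community)
    bounds = dict(medoid.bounds)
    probe = medoid.mu_seed if medoid.mu_seed else MU_PROBE
    for attempt in range(max_relaxations + 1):
        kwargs = ({"biomass_floor": bounds} if medoid.mode == "growth_rate"
                  else {"abundance_floor": bounds})
        mu = _bisect_max_growth(prob, mu_tol, kwargs, probe=probe)
        if mu is not None:
            notes = {"medoid_mode": medoid.mode,
                     "medoid_relaxations": attempt}
            return _finalize(prob, mu, kwargs, notes)
        bounds = {k: v * relax_factor for k, v in bounds.items()}
        logger.info("community %s: medoid floors infeasible, relaxing "
                    "(attempt %d)", community.id, attempt + 1)
    logger.warning("community %s: medoid floors never feasible, dropping",
                   community.id)
    sol = steadycom_max_growth(community, mu_tol=mu_tol, problem=prob)
    sol.notes["medoid_relaxations"] = max_relaxations
    sol.notes["medoid_dropped"] = True
    return sol


def l1_minimize(community: CommunityModel,
                solution: SteadyComSolution,
                problem: Optional[SteadyComProblem] = None
                ) -> SteadyComSolution:
    """Minimize Σ|V_j| at the solution's fixed μ and X.

    Removes futile cycles and extraneous flux while preserving every
    member's biomass flux (pinned by the μ·X coupling).
    """
    if solution.mu <= 0 or solution.status != "optimal":
        return solution
    prob = problem or SteadyComProblem(community)
    res = prob.solve(solution.mu, objective="l1", fixed_X=solution.X)
    if res["status"] != "optimal":
        logger.warning("community %s: L1 polish infeasible, returning input",
                       community.id)
        return solution
    X = np.array([solution.X[k] for k in community.members])
    out = prob.as_solution(solution.mu, X, res["V"],
                           notes={**solution.notes, "l1": True})
    return out
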