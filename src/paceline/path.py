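"""Piecewise structural equation modelling over the study's causal graph.

The path model is a directed acyclic graph whose endogenous nodes are each
fitted by the matching mixed model (Gaussian LMM, or binomial-logit GLMM
for the binary entry trait), with individual identity and prior-test count
as random intercepts.  Global goodness of fit uses the d-separation basis
set: every non-adjacent pair of variables that the DAG claims conditionally
independent is tested by adding the independent variable to the dependent
variable's regression, and the claim p-values combine into Fisher's

    C = -2 * sum log p_i  ~  chi2(2k),

which rejects when the data demand an omitted link.  Pairs declared as
correlated errors (the three-behaviour syndrome) and pairs of exogenous
variables (whose mutual association the DAG does not constrain) are
excluded from the basis set, following the piecewise-SEM convention.

Standardization: continuous variables are pre-scaled, two-level factors
coded -1/+1; binomial-node slopes are standardized on the latent scale as
beta * sd(x) / sd_latent with sd_latent^2 = var(fixed predictor) + random
intercept variances + pi^2/3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .glmm import BinomialLogitMixedModel, GLMMResults, LOGIT_LINK_VARIANCE
from .lmm import LinearMixedModel

__all__ = [
    "DagSpec",
    "IndependenceClaim",
    "PathModel",
    "PathModelResults",
    "build_dag",
    "basis_set",
    "fit_path_model",
    "compare_direction_variants",
    "NODE_COLUMNS",
]

# node -> (response column, predictor column) in the analysis table
NODE_COLUMNS: dict[str, tuple[str, str]] = {
    "birth_date": ("birth_z", "birth_z"),
    "year": ("year_code", "year_code"),
    "age_class": ("age_code", "age_code"),
    "temperature": ("temperature_z", "temperature_z"),
    "food": ("food_z", "food_z"),
    "body_mass": ("mass_z", "mass_z"),
    "entry": ("entry", "entry_z"),
    "distance": ("distance_z", "distance_z"),
    "exploration": ("exploration_z", "exploration_z"),
    "rmr": ("rmr_z", "rmr_z"),
    "stress_max": ("stress_max_z", "stress_max_z"),
    "stress_integral": ("stress_integral_z", "stress_integral_z"),
}

BEHAVIOUR_NODES = ("entry", "distance", "exploration")
_EXOG_DEFAULT = ("birth_date", "year", "age_class", "temperature", "food", "body_mass")


@dataclass
class DagSpec:
    """Directed acyclic graph plus correlated-error pairs and families."""

    nodes: dict  # name -> "gaussian" | "binomial-logit"
    edges: list  # (from, to)
    correlated_errors: list = field(default_factory=list)  # frozenset pairs
    exogenous: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.correlated_errors = [frozenset(p) for p in self.correlated_errors]
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"path specification contains a cycle: {cycle}")
        directed = {frozenset(e) for e in self.edges}
        for pair in self.correlated_errors:
            if pair in directed:
                raise ValueError(
                    f"correlated-error pair {set(pair)} is also connected by a directed edge"
                )

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @property
    def endogenous(self) -> list:
        g = self.graph()
        return [n for n in self.nodes if g.in_degree(n) > 0]


def build_dag(
    response: str = "rmr",
    direction: str = "forward",
    include_mass: bool = True,
    covariates: tuple[str, ...] = ("year", "age_class", "temperature", "food"),
) -> DagSpec:
    """The study's DAG for one metabolic response.

    ``forward`` (default): birth date and the environmental covariates feed
    the three behaviours; those plus birth date, covariates and body mass
    feed the metabolic response.  ``inverted`` swaps the purported causal
    direction between behaviours and the metabolic response.
    """
    if direction not in ("forward", "inverted"):
        raise ValueError("direction must be 'forward' or 'inverted'")
    nodes = {n: "gaussian" for n in ("birth_date", *covariates, "distance", "exploration", response)}
    nodes["entry"] = "binomial-logit"
    if include_mass:
        nodes["body_mass"] = "gaussian"
    edges = []
    upstream = ("birth_date", *covariates)
    for beh in BEHAVIOUR_NODES:
        edges += [(x, beh) for x in upstream]
    edges += [(x, response) for x in upstream]
    if include_mass:
        edges.append(("body_mass", response))
    if direction == "forward":
        edges += [(beh, response) for beh in BEHAVIOUR_NODES]
    else:
        edges += [(response, beh) for beh in BEHAVIOUR_NODES]
    correlated = [frozenset(p) for p in
                  (("entry", "distance"), ("entry", "exploration"), ("distance", "exploration"))]
    exog = ["birth_date", *covariates] + (["body_mass"] if include_mass else [])
    return DagSpec(nodes=nodes, edges=edges, correlated_errors=correlated, exogenous=exog)


@dataclass
class IndependenceClaim:
    """One d-separation claim: x independent of y given the conditioning set."""

    x: str
    y: str  # the dependent variable of the testing regression
    conditioning: tuple

    def __str__(self) -> str:
        cond = ", ".join(self.conditioning) or "{}"
        return f"{self.x} _||_ {self.y} | {cond}"


def basis_set(dag: DagSpec) -> list[IndependenceClaim]:
    """The directed-separation basis set of the DAG.

    One claim per non-adjacent pair, conditioned on the union of both
    variables' parents; the regression runs toward the variable that is not
    an ancestor of the other (preferring an endogenous dependent).  Pairs
    covered by a correlated error, and pairs of two exogenous variables,
    are excluded.
    """
    g = dag.graph()
    order = list(nx.topological_sort(g))
    adjacent = {frozenset(e) for e in dag.edges}
    exog = set(dag.exogenous)
    claims = []
    names = list(dag.nodes)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pair = frozenset((a, b))
            if pair in adjacent or pair in dag.correlated_errors:
                continue
            if a in exog and b in exog:
                continue
            # orient: dependent must not be an ancestor of the independent
            x, y = (a, b) if order.index(a) < order.index(b) else (b, a)
            if x in exog and y in exog:
                continue
            if y in exog:  # regression needs an endogenous-style dependent
                x, y = y, x
            cond = (set(g.predecessors(x)) | set(g.predecessors(y))) - {x, y}
            claims.append(IndependenceClaim(x=x, y=y, conditioning=tuple(sorted(cond))))
    return claims


# ---------------------------------------------------------------------------


def _fit_node(node: str, parents: list, data: pd.DataFrame, family: str,
              random_groups: tuple[str, ...] = ("individual_id", "test_number")):
    """Fit one component mixed model; returns (results, kept, dropped)."""
    response_col = NODE_COLUMNS[node][0]
    cols, kept, dropped = [], [], []
    for p_ in parents:
        col = NODE_COLUMNS[p_][1]
        if data[col].std(ddof=0) < 1e-12:
            dropped.append(p_)
        else:
            cols.append(col)
            kept.append(p_)
    # a variance component needs >= 3 levels to be estimable at all; with
    # fewer the factor is dropped (a 2-level "random" session effect is not
    # separable from session-aligned covariates and miscalibrates the tests)
    groups = [g for g in random_groups if data[g].nunique() >= 3]
    if "individual_id" in random_groups and "individual_id" not in groups:
        groups.insert(0, "individual_id")
    cls = LinearMixedModel if family == "gaussian" else BinomialLogitMixedModel
    fit = cls.from_dataframe(data, response_col, cols, groups).fit()
    return fit, kept, dropped


def _standardized(fit, term_col: str, data: pd.DataFrame) -> tuple[float, float, float]:
    """(beta_std, se_std, p) for one term; latent-scale for binomial fits."""
    j = fit.exog_names.index(term_col)
    beta, se, p = fit.params[j], fit.bse[j], fit.pvalues[j]
    if isinstance(fit, GLMMResults):
        sd_x = data[term_col].std(ddof=1)
        sd_lat = np.sqrt(np.var(fit.fittedvalues) + sum(fit.vc.values()) + LOGIT_LINK_VARIANCE)
        scale = sd_x / sd_lat
        return float(beta * scale), float(se * scale), float(p)
    return float(beta), float(se), float(p)


def _marginal_r2(fit) -> float:
    v_fix = float(np.var(fit.fittedvalues))
    if isinstance(fit, GLMMResults):
        total = v_fix + sum(fit.vc.values()) + LOGIT_LINK_VARIANCE
    else:
        total = v_fix + sum(fit.vc.values()) + fit.sigma2_resid
    return v_fix / total


@dataclass
class PathModelResults:
    """Fitted piecewise SEM: standardized coefficients and global fit."""

    dag: DagSpec
    coefficients: pd.DataFrame  # source, target, beta, se, p, family
    fisher_c: float
    fisher_df: int
    fisher_p: float
    marginal_r2: dict
    basis_claims: pd.DataFrame  # x, y, conditioning, p
    correlated_errors: pd.DataFrame  # a, b, r, p
    dropped_covariates: dict

    def coefficient(self, source: str, target: str) -> float:
        m = self.coefficients
        row = m[(m["source"] == source) & (m["target"] == target)]
        if row.empty:
            raise KeyError(f"no edge {source} -> {target}")
        return float(row["beta"].iloc[0])

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.to_dict(orient="records"),
            "fisher_c": self.fisher_c,
            "fisher_df": self.fisher_df,
            "fisher_p": self.fisher_p,
            "marginal_r2": self.marginal_r2,
            "basis_set": self.basis_claims.to_dict(orient="records"),
            "correlated_errors": self.correlated_errors.to_dict(orient="records"),
            "dropped_covariates": self.dropped_covariates,
        }

    def edge_list(self) -> pd.DataFrame:
        """Edge table for graph-drawing tools (weight = standardized beta)."""
        out = self.coefficients[["source", "target", "beta", "p"]].copy()
        out["significant"] = out["p"] < 0.05
        return out

    def summary(self) -> str:
        lines = ["Piecewise SEM", "=" * 64]
        lines.append(f"{'edge':<36}{'beta':>8}{'se':>8}{'p':>8}")
        for _, r in self.coefficients.iterrows():
            lines.append(f"{r['source'] + ' -> ' + r['target']:<36}"
                         f"{r['beta']:>8.3f}{r['se']:>8.3f}{r['p']:>8.4f}")
        lines.append("-" * 64)
        for a, b in [tuple(sorted(p)) for p in self.dag.correlated_errors]:
            m = self.correlated_errors
            row = m[(m["a"] == a) & (m["b"] == b)]
            if not row.empty:
                lines.append(f"corr.err {a} ~~ {b}: r = {row['r'].iloc[0]:.3f}")
        lines.append(f"Fisher's C = {self.fisher_c:.2f}, df = {self.fisher_df}, "
                     f"p = {self.fisher_p:.3f}")
        for node, r2 in self.marginal_r2.items():
            lines.append(f"marginal R2[{node}] = {r2:.3f}")
        return "\n".join(lines)


class PathModel:
    """Model object binding a DAG specification to an analysis table.

    ``data`` is the standardized session table from
    :func:`paceline.inference.prepare_analysis_table`.
    """

    def __init__(self, dag: DagSpec, data: pd.DataFrame,
                 random_groups: tuple[str, ...] = ("individual_id", "test_number")):
        self.dag = dag
        self.data = data
        self.random_groups = random_groups
        used = {NODE_COLUMNS[n][c] for n in dag.nodes for c in (0, 1)}
        missing = used - set(data.columns)
        if missing:
            raise ValueError(f"analysis table lacks columns {sorted(missing)}")
        if data[sorted(used)].isna().any().any():
            raise ValueError("missing values in path-model columns; filter sessions first")

    def fit(self, compute_fit: bool = True) -> PathModelResults:
        dag, data = self.dag, self.data
        g = dag.graph()
        rows, r2, dropped_all, fits = [], {}, {}, {}
        for node in dag.endogenous:
            parents = sorted(g.predecessors(node))
            family = dag.nodes[node]
            try:
                fit, kept, dropped = _fit_node(node, parents, data, family, self.random_groups)
            except Exception as err:
                raise RuntimeError(f"component model for node {node!r} failed: {err}") from err
            fits[node] = fit
            if dropped:
                dropped_all[node] = dropped
            for p_ in kept:
                beta, se, pval = _standardized(fit, NODE_COLUMNS[p_][1], data)
                rows.append({"source": p_, "target": node, "beta": beta, "se": se,
                             "p": pval, "family": family})
            r2[node] = _marginal_r2(fit)
        coefficients = pd.DataFrame(rows)

        claims_rows = []
        c_stat, k = 0.0, 0
        if compute_fit:
            for claim in basis_set(dag):
                pval = self._claim_pvalue(claim)
                claims_rows.append({"x": claim.x, "y": claim.y,
                                    "conditioning": ", ".join(claim.conditioning), "p": pval})
                c_stat += -2.0 * np.log(max(pval, 1e-300))
                k += 1
        fisher_p = float(stats.chi2.sf(c_stat, 2 * k)) if k else 1.0
        return PathModelResults(
            dag=dag,
            coefficients=coefficients,
            fisher_c=float(c_stat),
            fisher_df=2 * k,
            fisher_p=fisher_p,
            marginal_r2=r2,
            basis_claims=pd.DataFrame(claims_rows, columns=["x", "y", "conditioning", "p"]),
            correlated_errors=self._correlated_errors(fits),
            dropped_covariates=dropped_all,
        )

    def _claim_pvalue(self, claim: IndependenceClaim) -> float:
        """Test one claim: add x to the regression of y on its conditioning set."""
        dag, data = self.dag, self.data
        family = dag.nodes[claim.y]
        parents = list(claim.conditioning) + [claim.x]
        fit, kept, _ = _fit_node(claim.y, parents, data, family, self.random_groups)
        if claim.x not in kept:
            return 1.0
        j = fit.exog_names.index(NODE_COLUMNS[claim.x][1])
        return float(fit.pvalues[j])

    def _correlated_errors(self, fits: dict) -> pd.DataFrame:
        """Residual correlations among the correlated-error pairs."""
        resid = {}
        for node, fit in fits.items():
            if isinstance(fit, GLMMResults):
                resid[node] = fit.response_residuals()
            else:
                resid[node] = fit.conditional_residuals()
        rows = []
        for pair in self.dag.correlated_errors:
            a, b = sorted(pair)
            if a in resid and b in resid:
                r, p = stats.pearsonr(resid[a], resid[b])
                rows.append({"a": a, "b": b, "r": float(r), "p": float(p)})
        return pd.DataFrame(rows, columns=["a", "b", "r", "p"])


def fit_path_model(dag: DagSpec, data: pd.DataFrame, compute_fit: bool = True,
                   random_groups: tuple[str, ...] = ("individual_id", "test_number")
                   ) -> PathModelResults:
    """Functional wrapper over :class:`PathModel`."""
    return PathModel(dag, data, random_groups).fit(compute_fit=compute_fit)


def compare_direction_variants(
    data: pd.DataFrame,
    response: str = "rmr",
    alpha: float = 0.05,
    compute_fit: bool = True,
) -> dict:
    """Fit the forward and inverted DAGs and compare birth-date conclusions.

    Agreement holds when every birth-date edge shared by the two variants
    has the same sign and the same significance verdict at ``alpha``.
    """
    results = {}
    for direction in ("forward", "inverted"):
        dag = build_dag(response=response, direction=direction)
        results[direction] = fit_path_model(dag, data, compute_fit=compute_fit)
    agree = True
    details = []
    for target in (*BEHAVIOUR_NODES, response):
        row_f = results["forward"].coefficients.query(
            "source == 'birth_date' and target == @target")
        row_i = results["inverted"].coefficients.query(
            "source == 'birth_date' and target == @target")
        if row_f.empty or row_i.empty:
            continue
        bf, pf = float(row_f["beta"].iloc[0]), float(row_f["p"].iloc[0])
        bi, pi_ = float(row_i["beta"].iloc[0]), float(row_i["p"].iloc[0])
        same = (np.sign(bf) == np.sign(bi)) and ((pf < alpha) == (pi_ < alpha))
        agree &= same
        details.append({"target": target, "beta_forward": bf, "p_forward": pf,
                        "beta_inverted": bi, "p_inverted": pi_, "agree": bool(same)})
    return {"forward": results["forward"], "inverted": results["inverted"],
            "agreement": bool(agree), "details": pd.DataFrame(details)}
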