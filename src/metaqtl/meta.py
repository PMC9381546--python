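"""Meta-QTL detection on one chromosome.

Two branches, dispatched on the number of projected QTL:

* more than nine QTL: a Gaussian mixture with *known* per-observation
  variances (each QTL contributes its own sd from its 95% CI) is fitted by
  EM for K = 1..K_max; the number of components is chosen by a vote of five
  information criteria, requiring agreement of at least three;
* nine or fewer QTL: the ordered QTL are partitioned into contiguous blocks
  by exact dynamic programming, and the block count is chosen among
  {1, 2, 3, 4, n} by a penalized-likelihood criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import DomainError
from .types import GeneticMap, MetaQtl, ProjectedQtl

CRITERIA = ("AIC", "AICc", "AIC3", "BIC", "AWE")

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class MixtureModel:
    """A fitted K-component mixture with known per-observation variances."""

    K: int
    means: np.ndarray
    weights: np.ndarray
    logL: float
    responsibilities: np.ndarray
    converged: bool
    n_obs: int


@dataclass
class CriteriaRow:
    K: int
    nu: int
    AIC: float
    AICc: float
    AIC3: float
    BIC: float
    AWE: float

    def value(self, name: str) -> float:
        return getattr(self, name)


@dataclass
class ChromosomeDecision:
    """Audit record of the model choice made for one chromosome."""

    chromosome: int
    n_qtl: int
    branch: str  # "mixture" or "contiguous"
    chosen_k: int
    model_label: str
    criteria: list[dict] = field(default_factory=list)
    votes: dict = field(default_factory=dict)
    vote_counts: dict = field(default_factory=dict)
    rule: str = ""

    def to_dict(self) -> dict:
        return {
            "chromosome": self.chromosome,
            "n_qtl": self.n_qtl,
            "branch": self.branch,
            "chosen_k": self.chosen_k,
            "model_label": self.model_label,
            "criteria": self.criteria,
            "votes": self.votes,
            "vote_counts": self.vote_counts,
            "rule": self.rule,
        }


def _log_norm_matrix(x: np.ndarray, s: np.ndarray, means: np.ndarray) -> np.ndarray:
    """log φ(x_i; μ_k, s_i²) as an (n, K) matrix."""
    z = (x[:, None] - means[None, :]) / s[:, None]
    return -0.5 * z * z - np.log(s)[:, None] - 0.5 * _LOG_2PI


def mixture_loglik(
    x: np.ndarray, s: np.ndarray, means: np.ndarray, weights: np.ndarray
) -> float:
    """Observed-data log-likelihood of a known-variance Gaussian mixture."""
    lp = _log_norm_matrix(x, s, means) + np.log(weights)[None, :]
    return float(logsumexp(lp, axis=1).sum())


def _em_single(
    x: np.ndarray,
    s: np.ndarray,
    means0: np.ndarray,
    weights0: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, bool]:
    means = means0.astype(float).copy()
    weights = weights0.astype(float).copy()
    inv_var = 1.0 / (s * s)
    n = x.size
    prev = -np.inf
    converged = False
    resp = np.ones((n, means.size)) / means.size
    for _ in range(max_iter):
        lp = _log_norm_matrix(x, s, means) + np.log(weights)[None, :]
        norm = logsumexp(lp, axis=1)
        logL = float(norm.sum())
        # EM ascent property; tiny slack for float round-off
        assert logL >= prev - 1e-9 * (1.0 + abs(prev)), "EM log-likelihood decreased"
        resp = np.exp(lp - norm[:, None])
        if logL - prev < tol and np.isfinite(prev):
            converged = True
            prev = logL
            break
        prev = logL
        wsum = resp.sum(axis=0)
        num = (resp * (x * inv_var)[:, None]).sum(axis=0)
        den = (resp * inv_var[:, None]).sum(axis=0)
        keep = den > 0
        means[keep] = num[keep] / den[keep]
        weights = np.maximum(wsum / n, 1e-12)
        weights /= weights.sum()
    return means, weights, prev, resp, converged


def em_fit(
    x: np.ndarray,
    s: np.ndarray,
    K: int,
    n_starts: int = 10,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> MixtureModel:
    """Fit a K-component mixture with known per-observation sds by EM.

    The first start spreads the means on the quantiles of x; remaining starts
    draw means from the data range with a generator seeded by ``seed``, so
    the fit is reproducible.  The best start by log-likelihood wins.
    Components are returned with means sorted ascending.
    """
    x = np.asarray(x, dtype=float)
    s = np.asarray(s, dtype=float)
    if x.size == 0:
        raise DomainError("empty input")
    if x.size != s.size:
        raise DomainError("x and s must have equal length")
    if np.any(s <= 0):
        raise DomainError("all sds must be > 0")
    if not 1 <= K <= x.size:
        raise DomainError(f"K must be in 1..{x.size}, got {K}")

    if K == 1:
        # closed form: inverse-variance weighted mean
        w = 1.0 / (s * s)
        mean = np.array([float(np.sum(w * x) / np.sum(w))])
        weights = np.array([1.0])
        logL = mixture_loglik(x, s, mean, weights)
        return MixtureModel(1, mean, weights, logL, np.ones((x.size, 1)), True, x.size)

    rng = np.random.default_rng(seed)
    q = (np.arange(K) + 0.5) / K
    inits = [np.quantile(x, q)]
    lo, hi = float(x.min()), float(x.max())
    span = hi - lo if hi > lo else 1.0
    for _ in range(max(0, n_starts - 1)):
        inits.append(np.sort(lo + span * rng.random(K)))

    best: tuple[float, np.ndarray, np.ndarray, np.ndarray, bool] | None = None
    w0 = np.full(K, 1.0 / K)
    for means0 in inits:
        means, weights, logL, resp, conv = _em_single(x, s, means0, w0, max_iter, tol)
        if best is None or logL > best[0]:
            best = (logL, means, weights, resp, conv)
    logL, means, weights, resp, conv = best
    order = np.argsort(means, kind="stable")
    return MixtureModel(
        K=K,
        means=means[order],
        weights=weights[order],
        logL=logL,
        responsibilities=resp[:, order],
        converged=conv,
        n_obs=x.size,
    )


def information_criteria(model: MixtureModel) -> CriteriaRow:
    """Five penalized-likelihood criteria for a fitted mixture.

    Free parameters ν = 2K − 1 (K means and K − 1 weights; the observation
    variances are known, not estimated).
    """
    K, n, logL = model.K, model.n_obs, model.logL
    nu = 2 * K - 1
    aic = -2.0 * logL + 2.0 * nu
    aicc = aic + 2.0 * nu * (nu + 1) / (n - nu - 1) if n - nu - 1 > 0 else math.inf
    aic3 = -2.0 * logL + 3.0 * nu
    bic = -2.0 * logL + nu * math.log(n)
    awe = -2.0 * logL + 2.0 * nu * (1.5 + math.log(n))
    return CriteriaRow(K=K, nu=nu, AIC=aic, AICc=aicc, AIC3=aic3, BIC=bic, AWE=awe)


def select_k(rows: list[CriteriaRow]) -> tuple[int, dict]:
    """Choose K by criterion vote.

    Each of the five criteria votes for its minimizing K (ties toward the
    smaller K).  The chosen K is the smallest one collecting at least three
    votes; if no K does, the plurality winner is taken (ties toward the
    smaller K).  The full decision path is returned alongside.
    """
    if not rows:
        raise DomainError("empty criteria table")
    rows = sorted(rows, key=lambda r: r.K)
    votes: dict[str, int] = {}
    for name in CRITERIA:
        votes[name] = min(rows, key=lambda r: (r.value(name), r.K)).K
    counts: dict[int, int] = {}
    for k in votes.values():
        counts[k] = counts.get(k, 0) + 1
    majority = sorted(k for k, c in counts.items() if c >= 3)
    if majority:
        chosen, rule = majority[0], "at_least_three_of_five"
    else:
        top = max(counts.values())
        chosen = min(k for k, c in counts.items() if c == top)
        rule = "plurality_fallback"
    record = {
        "votes": votes,
        "vote_counts": {int(k): int(c) for k, c in sorted(counts.items())},
        "rule": rule,
    }
    return chosen, record


def _block_stats(x: np.ndarray, inv_var: np.ndarray, i: int, j: int) -> tuple[float, float]:
    """(inverse-variance mean, Gaussian log-likelihood) of block x[i:j]."""
    w = inv_var[i:j]
    xb = x[i:j]
    mu = float(np.sum(w * xb) / np.sum(w))
    z2 = (xb - mu) ** 2 * w
    ll = float(-0.5 * np.sum(z2) + 0.5 * np.sum(np.log(w)) - 0.5 * (j - i) * _LOG_2PI)
    return mu, ll


def gg_cluster(
    x: np.ndarray, s: np.ndarray, k: int
) -> tuple[list[tuple[int, int]], float]:
    """Optimal partition of sorted positions into k contiguous blocks.

    Maximizes the summed Gaussian log-likelihood with each block centred on
    its inverse-variance mean; solved exactly by dynamic programming over
    block boundaries.  Ties are broken toward the leftmost boundaries.
    Returns ([(start, end), ...] half-open index blocks, total logL).
    """
    x = np.asarray(x, dtype=float)
    s = np.asarray(s, dtype=float)
    n = x.size
    if not 1 <= k <= n:
        raise DomainError(f"k must be in 1..{n}, got {k}")
    if np.any(np.diff(x) < 0):
        raise DomainError("x must be sorted ascending")
    inv_var = 1.0 / (s * s)

    score = np.full((n + 1, n + 1), -np.inf)
    for i in range(n):
        for j in range(i + 1, n + 1):
            score[i][j] = _block_stats(x, inv_var, i, j)[1]

    # g[i][m]: best total logL splitting x[i:] into m blocks
    g = np.full((n + 1, k + 1), -np.inf)
    g[n][0] = 0.0
    for m in range(1, k + 1):
        for i in range(n - 1, -1, -1):
            for j in range(i + 1, n - m + 2):
                cand = score[i][j] + g[j][m - 1]
                if cand > g[i][m]:
                    g[i][m] = cand

    blocks: list[tuple[int, int]] = []
    i, m = 0, k
    eps = 1e-9
    while m > 0:
        for j in range(i + 1, n - m + 2):
            if score[i][j] + g[j][m - 1] >= g[i][m] - eps * (1.0 + abs(g[i][m])):
                blocks.append((i, j))
                i, m = j, m - 1
                break
    return blocks, float(g[0][k])


def gg_select(
    x: np.ndarray, s: np.ndarray
) -> tuple[int, list[tuple[int, int]], dict]:
    """Choose the number of contiguous blocks among candidates {1,2,3,4,n}.

    Each candidate k is scored by C(k) = −2 logL(k) + 2 k ln n; the minimizer
    wins (ties toward the smaller k).  The winning model is labelled
    "Model m" (or "Model n" when the every-QTL-apart model wins).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 1:
        raise DomainError("empty input")
    candidates = sorted({k for k in (1, 2, 3, 4, n) if 1 <= k <= n})
    table = []
    results: dict[int, list[tuple[int, int]]] = {}
    for k in candidates:
        blocks, logL = gg_cluster(x, s, k)
        crit = -2.0 * logL + 2.0 * k * math.log(n) if n > 1 else -2.0 * logL
        table.append({"k": k, "logL": logL, "criterion": crit})
        results[k] = blocks
    chosen = min(table, key=lambda r: (r["criterion"], r["k"]))["k"]
    label = "Model n" if (chosen == n and n > 4) else f"Model {chosen}"
    record = {"criteria": table, "chosen_k": chosen, "model_label": label}
    return chosen, results[chosen], record


def summarize_mqtl(
    members: list[ProjectedQtl],
    weight: float,
    consensus: GeneticMap | None,
    mqtl_id: str,
    responsibilities: np.ndarray | None = None,
) -> MetaQtl:
    """Condense member QTL into one consensus locus.

    Position is the inverse-variance mean of member positions (weighted by
    responsibilities in the mixture branch); the meta sd combines member
    precisions, and the 95% CI is position ± 1.96 × sd.  The peak marker is
    the consensus marker nearest the position, and the flanking markers the
    nearest ones outside the CI on each side.
    """
    if not members:
        raise DomainError("an MQTL needs at least one member")
    w = (
        np.ones(len(members))
        if responsibilities is None
        else np.asarray(responsibilities, dtype=float)
    )
    xs = np.array([m.position for m in members])
    prec = w / np.array([m.sigma for m in members]) ** 2
    position = float(np.sum(prec * xs) / np.sum(prec))
    sigma_meta = float(math.sqrt(1.0 / np.sum(prec)))
    ci_lo, ci_hi = position - 1.96 * sigma_meta, position + 1.96 * sigma_meta
    chrom = members[0].chromosome
    peak = flank_l = flank_r = None
    if consensus is not None:
        peak = consensus.nearest_marker(chrom, position)
        flank_l, flank_r = consensus.flanking_markers(chrom, ci_lo, ci_hi)
    return MetaQtl(
        mqtl_id=mqtl_id,
        chromosome=chrom,
        position=position,
        ci95_start=ci_lo,
        ci95_end=ci_hi,
        weight=float(weight),
        member_qtl=[m.qtl_id for m in members],
        sigma=sigma_meta,
        peak_marker=peak,
        flank_left=flank_l,
        flank_right=flank_r,
    )


#: chromosomes with more QTL than this use the mixture branch
MIXTURE_THRESHOLD = 9


def analyze_chromosome(
    qtls: list[ProjectedQtl],
    k_max: int = 10,
    consensus: GeneticMap | None = None,
    n_starts: int = 10,
    seed: int = 0,
) -> tuple[list[MetaQtl], ChromosomeDecision]:
    """Detect meta-QTL on one chromosome and record how the model was chosen."""
    if not qtls:
        raise DomainError("no projected QTL supplied")
    qtls = sorted(qtls, key=lambda q: (q.position, q.qtl_id))
    chrom = qtls[0].chromosome
    x = np.array([q.position for q in qtls])
    s = np.array([q.sigma for q in qtls])
    n = len(qtls)

    if n > MIXTURE_THRESHOLD:
        models = {
            K: em_fit(x, s, K, n_starts=n_starts, seed=seed + K)
            for K in range(1, min(k_max, n) + 1)
        }
        rows = [information_criteria(m) for m in models.values()]
        chosen, record = select_k(rows)
        model = models[chosen]
        assignment = np.argmax(model.responsibilities, axis=1)
        mqtls = []
        for k in range(chosen):
            idx = np.where(assignment == k)[0]
            if idx.size == 0:
                continue
            mqtls.append(
                summarize_mqtl(
                    [qtls[i] for i in idx],
                    weight=float(model.weights[k]),
                    consensus=consensus,
                    mqtl_id=f"MQTL{chrom}.{len(mqtls) + 1}",
                    responsibilities=model.responsibilities[idx, k],
                )
            )
        decision = ChromosomeDecision(
            chromosome=chrom,
            n_qtl=n,
            branch="mixture",
            chosen_k=chosen,
            model_label=f"K={chosen}",
            criteria=[vars(r).copy() for r in rows],
            votes=record["votes"],
            vote_counts=record["vote_counts"],
            rule=record["rule"],
        )
    else:
        chosen, blocks, record = gg_select(x, s)
        mqtls = []
        for b, (i, j) in enumerate(blocks, start=1):
            mqtls.append(
                summarize_mqtl(
                    qtls[i:j],
                    weight=(j - i) / n,
                    consensus=consensus,
                    mqtl_id=f"MQTL{chrom}.{b}",
                )
            )
        decision = ChromosomeDecision(
            chromosome=chrom,
            n_qtl=n,
            branch="contiguous",
            chosen_k=chosen,
            model_label=record["model_label"],
            criteria=record["criteria"],
            rule="min_penalized_likelihood",
        )
    mqtls.sort(key=lambda m: m.position)
    for i, m in enumerate(mqtls, start=1):
        m.mqtl_id = f"MQTL{chrom}.{i}"
    return mqtls, decision


def analyze_genome(
    projected: list[ProjectedQtl],
    k_max: int = 10,
    consensus: GeneticMap | None = None,
    n_starts: int = 10,
    seed: int = 0,
) -> tuple[list[MetaQtl], list[ChromosomeDecision]]:
    """Run the per-chromosome analysis over a whole projected compilation."""
    by_chrom: dict[int, list[ProjectedQtl]] = {}
    for q in projected:
        by_chrom.setdefault(q.chromosome, []).append(q)
    mqtls: list[MetaQtl] = []
    decisions: list[ChromosomeDecision] = []
    for chrom in sorted(by_chrom):
        found, decision = analyze_chromosome(
            by_chrom[chrom],
            k_max=k_max,
            consensus=consensus,
            n_starts=n_starts,
            seed=seed + 1000 * chrom,
        )
        mqtls.extend(found)
        decisions.append(decision)
    return mqtls, decisions
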