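"""Multinomial likelihood for maternal transmission ratio distortion.

The model treats each family (genotyped dam, genotyped offspring,
ungenotyped sire from variety E or R) as an independent multinomial draw
over the offspring genotype.  For a biallelic SNP with alleles A1/A2, the
dam transmits A1 with probability

* 1        if she is A1A1 (code 2),
* 0.5 + a  if she is heterozygous (code 1) — ``a`` is the distortion
  parameter, 0 under Mendelian segregation,
* 0        if she is A2A2 (code 0),

and the sire contributes A1 with probability pi_E or pi_R, the A1 frequency
among the sires of his variety.  Offspring genotype probabilities are the
products/sums of these two transmissions.  The parameters (a, pi_E, pi_R)
are estimated per SNP by gradient ascent on reparameterized (unbounded)
coordinates with deterministic restarts, and the distortion is tested with
a likelihood ratio against the a = 0 null (chi-square, 1 df).

``a`` is bounded inside (-0.5, 0.5) at +/-0.495 so every transmission
probability stays strictly positive; extreme SNPs therefore report +/-0.495.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .family_data import MISSING, FamilySet, GenotypeTable

__all__ = [
    "ALPHA_BOUND",
    "SIRE_VARIETIES",
    "TransmissionCounts",
    "TRDFit",
    "NullFit",
    "offspring_probs",
    "tabulate",
    "loglik",
    "fit_null",
    "fit_full",
    "lrt_pvalue",
]

ALPHA_BOUND = 0.495
SIRE_VARIETIES = ("E", "R")
_SIRE_INDEX = {"E": 0, "R": 1}


@dataclass
class TransmissionCounts:
    """Per-SNP sufficient statistics.

    ``n[d, o, s]`` counts complete, Mendelian-compatible families with dam
    genotype d, offspring genotype o and sire variety s (axis order E, R).
    Opposite-homozygote cells n[2,0,:] and n[0,2,:] are structurally zero.
    """

    n: np.ndarray  # (3, 3, 2) non-negative ints

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.int64)
        if self.n.shape != (3, 3, 2):
            raise ValueError(f"counts must be (3,3,2), got {self.n.shape}")
        if (self.n < 0).any():
            raise ValueError("negative counts")
        if self.n[2, 0, :].any() or self.n[0, 2, :].any():
            raise ValueError("incompatible dam-offspring cells must be zero")

    @property
    def total(self) -> int:
        return int(self.n.sum())

    def n_sire(self, variety: str) -> int:
        return int(self.n[:, :, _SIRE_INDEX[variety]].sum())

    @property
    def n_het_dam(self) -> int:
        return int(self.n[1].sum())


@dataclass
class TRDFit:
    """Full-model ML estimates for one SNP.

    ``pi_e``/``pi_r`` are NaN when no family of that sire variety is
    present (the parameter is dropped from the optimization).
    """

    alpha: float
    pi_e: float
    pi_r: float
    lnl: float
    converged: bool = True
    n_restarts_used: int = 0
    estimable: bool = True


@dataclass
class NullFit:
    """Null-model (alpha = 0) ML estimates."""

    pi_e: float
    pi_r: float
    lnl: float
    estimable: bool = True


def offspring_probs(dam_genotype: int, alpha: float, pi: float) -> tuple[float, float, float]:
    """Probabilities (p0, p1, p2) of the offspring's A1 dosage.

    p2 = p_dam(A1) * pi, p1 = p_dam(A1)*(1-pi) + p_dam(A2)*pi,
    p0 = p_dam(A2) * (1-pi), with p_dam(A1) = 1, 0.5+alpha, 0 for dam
    genotypes 2, 1, 0.  Always sums to 1.
    """
    if dam_genotype == 2:
        pm = 1.0
    elif dam_genotype == 1:
        pm = 0.5 + alpha
    elif dam_genotype == 0:
        pm = 0.0
    else:
        raise ValueError(f"dam genotype must be 0, 1 or 2, got {dam_genotype}")
    qm = 1.0 - pm
    return (qm * (1.0 - pi), pm * (1.0 - pi) + qm * pi, pm * pi)


def tabulate(
    snp_row: np.ndarray,
    families: FamilySet | list[tuple[int, int, str]],
    table: GenotypeTable | None = None,
) -> TransmissionCounts:
    """Count complete, compatible (dam, offspring, sire-variety) cells.

    ``families`` may be a FamilySet (then ``table`` is required to resolve
    ids to columns) or pre-resolved (offspring_col, dam_col, variety)
    triples.  Incomplete and Mendelian-incompatible pairs are excluded.
    """
    if isinstance(families, FamilySet):
        if table is None:
            raise ValueError("table required to resolve a FamilySet")
        families = families.resolve(table)
    n = np.zeros((3, 3, 2), dtype=np.int64)
    for off_col, dam_col, variety in families:
        d, o = int(snp_row[dam_col]), int(snp_row[off_col])
        if d == MISSING or o == MISSING:
            continue
        if (d == 2 and o == 0) or (d == 0 and o == 2):
            continue
        n[d, o, _SIRE_INDEX[variety]] += 1
    return TransmissionCounts(n)


def loglik(counts: TransmissionCounts, alpha: float, pi_e: float, pi_r: float) -> float:
    """Log-likelihood sum_{d,o,s} n[d,o,s] * ln p_o(d, alpha, pi_s).

    Cells with n = 0 contribute nothing even where p = 0; a populated cell
    with p = 0 yields -inf.
    """
    n = counts.n
    total = 0.0
    for s, pi in ((0, pi_e), (1, pi_r)):
        if np.isnan(pi):
            if n[:, :, s].any():
                raise ValueError("pi is NaN but families of that variety exist")
            continue
        for d in range(3):
            probs = offspring_probs(d, alpha, pi)
            for o in range(3):
                c = n[d, o, s]
                if c:
                    p = probs[o]
                    if p <= 0.0:
                        return float("-inf")
                    total += c * math.log(p)
    return total


def fit_null(counts: TransmissionCounts) -> NullFit:
    """Maximize the likelihood at alpha = 0 over (pi_E, pi_R).

    With alpha fixed at 0 the likelihood factorizes by sire variety and
    each pi is a binomial proportion: cells where the offspring received a
    paternal A1 (dam 2 / off 2, dam 0 / off 1, dam 1 / off 2) versus a
    paternal A2 (dam 2 / off 1, dam 0 / off 0, dam 1 / off 0); het-dam /
    het-offspring cells have probability 1/2 regardless of pi.  A variety
    with no families reports pi = NaN.
    """
    n = counts.n
    if counts.total == 0:
        return NullFit(float("nan"), float("nan"), 0.0, estimable=False)
    pis = []
    for s in range(2):
        if n[:, :, s].sum() == 0:
            pis.append(float("nan"))
            continue
        a = n[2, 2, s] + n[0, 1, s] + n[1, 2, s]  # paternal A1 observed
        b = n[2, 1, s] + n[0, 0, s] + n[1, 0, s]  # paternal A2 observed
        pis.append(0.5 if a + b == 0 else a / (a + b))
    pi_e, pi_r = pis
    return NullFit(pi_e, pi_r, loglik(counts, 0.0, pi_e, pi_r))


# ---------------------------------------------------------------------------
# Full-model fit: gradient ascent on reparameterized coordinates.
# alpha = ALPHA_BOUND * tanh(u), pi_s = sigmoid(v_s); analytic gradients.
# ---------------------------------------------------------------------------

_MAX_ITER = 10_000
_REL_TOL = 1e-10
_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def _lnl_and_grad(cells_by_s, active: list[int], alpha: float, pis: list[float]):
    """Log-likelihood and its gradient in (alpha, pi_active...) coordinates.

    Each cell probability is bilinear (see ``_CELL_COEF``), so
    dp/dalpha = ca + cap*pi and dp/dpi = cp + cap*alpha.
    """
    lnl = 0.0
    g_alpha = 0.0
    g_pi = [0.0, 0.0]
    for s in active:
        pi = pis[s]
        for c, c0, ca, cp, cap in cells_by_s[s]:
            p = c0 + ca * alpha + cp * pi + cap * alpha * pi
            if p <= 0.0:
                return float("-inf"), 0.0, [0.0, 0.0]
            lnl += c * math.log(p)
            g_alpha += c * (ca + cap * pi) / p
            g_pi[s] += c * (cp + cap * alpha) / p
    return lnl, g_alpha, g_pi


def _golden_max(f, lo: float, hi: float, tol: float = 1e-9) -> tuple[float, float]:
    """Golden-section maximization of a unimodal f on [lo, hi]."""
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
    x = c if fc >= fd else d
    return x, max(fc, fd)


def _ascend(cells_by_s, active: list[int], has_het: bool, start) -> tuple[float, list[float], float, bool]:
    """Gradient ascent from one start point; returns (alpha, pis, lnl, converged)."""
    alpha0, pi0 = start
    u = math.atanh(min(max(alpha0 / ALPHA_BOUND, -0.999), 0.999)) if has_het else 0.0
    v = [0.0, 0.0]
    for s in active:
        p = min(max(pi0[s], 1e-3), 1.0 - 1e-3)
        v[s] = math.log(p / (1.0 - p))

    def unpack():
        alpha = ALPHA_BOUND * math.tanh(u) if has_het else 0.0
        pis = [_sigmoid(v[s]) if s in active else float("nan") for s in range(2)]
        return alpha, pis

    alpha, pis = unpack()
    lnl, ga, gp = _lnl_and_grad(cells_by_s, active, alpha, pis)
    step = 0.25
    converged = False
    for _ in range(_MAX_ITER):
        # chain rule to unconstrained coordinates
        dadu = ALPHA_BOUND * (1.0 - math.tanh(u) ** 2) if has_het else 0.0
        gu = ga * dadu
        gv = [gp[s] * pis[s] * (1.0 - pis[s]) if s in active else 0.0 for s in range(2)]
        gnorm = math.sqrt(gu * gu + gv[0] ** 2 + gv[1] ** 2)
        if gnorm < 1e-12:
            converged = True
            break
        # backtracking line search along the gradient
        improved = False
        t = step
        for _bt in range(60):
            u_t = u + t * gu
            v_t = [v[s] + t * gv[s] for s in range(2)]
            alpha_t = ALPHA_BOUND * math.tanh(u_t) if has_het else 0.0
            pis_t = [_sigmoid(v_t[s]) if s in active else float("nan") for s in range(2)]
            lnl_t, ga_t, gp_t = _lnl_and_grad(cells_by_s, active, alpha_t, pis_t)
            if lnl_t > lnl:
                improved = True
                break
            t *= 0.5
        if not improved:
            converged = True
            break
        rel = (lnl_t - lnl) / (abs(lnl) + 1.0)
        u, v, alpha, pis = u_t, v_t, alpha_t, pis_t
        lnl, ga, gp = lnl_t, ga_t, gp_t
        step = min(t * 2.0, 64.0)
        if rel < _REL_TOL:
            converged = True
            break
    return alpha, pis, lnl, converged


# Every cell probability is bilinear in (alpha, pi):
# p(d, o) = c0 + ca*alpha + cp*pi + cap*alpha*pi.  Coefficients by (d, o):
_CELL_COEF = {
    (0, 0): (1.0, 0.0, -1.0, 0.0),
    (0, 1): (0.0, 0.0, 1.0, 0.0),
    (1, 0): (0.5, -1.0, -0.5, 1.0),
    (1, 1): (0.5, 1.0, 0.0, -2.0),
    (1, 2): (0.0, 0.0, 0.5, 1.0),
    (2, 1): (1.0, 0.0, -1.0, 0.0),
    (2, 2): (0.0, 0.0, 1.0, 0.0),
}


def _cells(n: np.ndarray, s: int) -> list[tuple[float, float, float, float, float]]:
    """Populated (count, c0, ca, cp, cap) cells for one sire variety."""
    return [
        (float(n[d, o, s]),) + _CELL_COEF[(d, o)]
        for (d, o) in _CELL_COEF
        if n[d, o, s]
    ]


def _lnl_cells(cells, alpha: float, pi: float) -> float:
    lnl = 0.0
    for c, c0, ca, cp, cap in cells:
        p = c0 + ca * alpha + cp * pi + cap * alpha * pi
        if p <= 0.0:
            return float("-inf")
        lnl += c * math.log(p)
    return lnl


def _profile_lnl(cells_by_s, active: list[int], alpha: float,
                 tol: float = 1e-8) -> tuple[float, list[float]]:
    """Profile log-likelihood at fixed alpha: each pi_s enters the per-cell
    probabilities linearly, so the per-variety term is concave in pi_s and
    golden section finds its unique maximizer."""
    pis = [float("nan"), float("nan")]
    total = 0.0
    for s in active:
        pis[s], val = _golden_max(
            lambda p, s=s: _lnl_cells(cells_by_s[s], alpha, p), 0.0, 1.0, tol
        )
        total += val
    return total, pis


def _coarse_profile_argmax(cells_by_s, active: list[int], step: float = 0.01) -> float:
    """Vectorized coarse scan of the alpha-profile likelihood (inner max
    over a matching pi grid)."""
    alphas = np.arange(-ALPHA_BOUND, ALPHA_BOUND + step / 2, step)
    pis = np.arange(0.0, 1.0 + step / 2, step)
    a_col = alphas[:, None]
    p_row = pis[None, :]
    total = np.zeros_like(alphas)
    with np.errstate(divide="ignore", invalid="ignore"):
        for s in active:
            g = np.zeros((alphas.size, pis.size))
            for c, c0, ca, cp, cap in cells_by_s[s]:
                g += c * np.log(c0 + ca * a_col + cp * p_row + cap * a_col * p_row)
            total += np.max(np.where(np.isfinite(g), g, -np.inf), axis=1)
    return float(alphas[int(np.argmax(total))])


def fit_full(counts: TransmissionCounts) -> TRDFit:
    """Maximize the likelihood over (alpha, pi_E, pi_R) with box constraints.

    Reparameterized gradient ascent (tanh for alpha on
    [-ALPHA_BOUND, ALPHA_BOUND], logit for each pi) with analytic
    gradients, run from 5 deterministic start points, then polished on the
    alpha-profile likelihood: a coarse alpha scan plus golden-section
    refinement, with the inner pi maximizations solved exactly (concave
    1-D problems).  The profile stage both reaches boundary optima that
    the soft reparameterization approaches only asymptotically and jumps
    out of coordinate-locked local modes.  Exact lnL ties go to the
    smallest ``|alpha|``.  Requires at least one heterozygous-dam family
    for alpha to be estimable.
    """
    n = counts.n
    active = [s for s in range(2) if n[:, :, s].sum() > 0]
    if not active:
        return TRDFit(float("nan"), float("nan"), float("nan"), 0.0, estimable=False)
    if counts.n_het_dam == 0:
        null = fit_null(counts)
        return TRDFit(float("nan"), null.pi_e, null.pi_r, null.lnl, estimable=False)

    null = fit_null(counts)
    pi_start = [
        min(max(p, 0.05), 0.95) if not np.isnan(p) else 0.5
        for p in (null.pi_e, null.pi_r)
    ]
    starts = [
        (0.0, pi_start),
        (0.25, [0.5, 0.5]),
        (-0.25, [0.5, 0.5]),
        (0.45, pi_start),
        (-0.45, pi_start),
    ]

    cells_by_s = [_cells(n, 0), _cells(n, 1)]
    best = None
    for k, start in enumerate(starts):
        alpha, pis, lnl, conv = _ascend(cells_by_s, active, True, start)
        cand = (lnl, -abs(alpha), alpha, pis, conv, k + 1)
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = cand
    lnl_asc, _, alpha_asc, _, conv, k_used = best

    # profile polish: coarse scan of the alpha-profile likelihood, then
    # golden refinement of the best coarse point and of the ascent's alpha
    a_coarse = _coarse_profile_argmax(cells_by_s, active)

    candidates = []
    for center, half in ((a_coarse, 0.011), (alpha_asc, 0.02)):
        lo = max(-ALPHA_BOUND, center - half)
        hi = min(ALPHA_BOUND, center + half)
        a_ref, _ = _golden_max(
            lambda a: _profile_lnl(cells_by_s, active, a)[0], lo, hi, tol=1e-8
        )
        lnl_ref, pis_ref = _profile_lnl(cells_by_s, active, a_ref, tol=1e-10)
        candidates.append((lnl_ref, -abs(a_ref), a_ref, pis_ref))
    lnl, _, alpha, pis = max(candidates, key=lambda c: (c[0], c[1]))
    if lnl < lnl_asc:  # never discard a better ascent result
        lnl, alpha = lnl_asc, alpha_asc
        _, pis = _profile_lnl(cells_by_s, active, alpha, tol=1e-10)

    return TRDFit(alpha, pis[0], pis[1], lnl, converged=conv, n_restarts_used=k_used)


def lrt_pvalue(full: TRDFit, null: NullFit) -> tuple[float, float]:
    """Likelihood ratio statistic 2*(lnL_full - lnL_null), clipped at 0,
    against chi-square with 1 df.  NaN for non-estimable fits."""
    if not (full.estimable and null.estimable):
        return float("nan"), float("nan")
    stat = max(0.0, 2.0 * (full.lnl - null.lnl))
    return stat, float(chi2.sf(stat, df=1))
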