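"""Maximum-likelihood fitting by simulated annealing, and AICc comparison.

The Bernoulli likelihood of each model is maximized with a
Kirkpatrick-style annealer: one proposed move per parameter per sweep,
Metropolis acceptance, geometric cooling, several independent restarts.
The random model has a closed-form maximum (p = L / (S_C * S_R)) and
bypasses annealing.  Likelihood deltas are evaluated incrementally — a
resource-position move touches one row of the probability matrix, a
consumer move one column — so fits of desk-scale networks take seconds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .models import (
    EPS, G_CAP, G_MIN, R_CAP,
    BPNMParams, CascadeParams, RandomParams,
    aicc, log_likelihood, parameter_count, probability_matrix,
)

__all__ = ["AnnealConfig", "FitResult", "fit_model", "compare_models", "sensitivity_profile"]

_R_MIN = 1e-3   # proposal floor for niche widths (r is an open interval at 0)
_P_JUMP = 0.1   # long-range proposal share; axis orderings are multimodal
_POLISH_SWEEPS = 400   # zero-temperature refinement budget after annealing
_POLISH_PATIENCE = 10  # stop after this many consecutive stagnant sweeps


@dataclass(frozen=True)
class AnnealConfig:
    """Annealing schedule; defaults sized for networks up to ~100x100.

    ``initial_temperature="auto"`` sets T0 to the standard deviation of
    the log-likelihood over 50 random-parameter probes.
    """

    n_sweeps: int = 400
    initial_temperature: float | str = "auto"
    cooling_factor: float = 0.95
    proposal_sd: float = 0.05
    n_restarts: int = 3
    seed: int = 0
    fix_g: float | None = None      # hold the cutoff-shape exponent fixed
    fix_p_max: float | None = None  # hold the peak probability fixed

    def __post_init__(self):
        if self.n_sweeps < 1 or self.n_restarts < 1:
            raise ValueError("n_sweeps and n_restarts must be positive")
        if not (0.0 < self.cooling_factor < 1.0):
            raise ValueError("cooling_factor must lie in (0, 1)")
        if self.proposal_sd <= 0:
            raise ValueError("proposal_sd must be positive")
        if self.initial_temperature != "auto" and self.initial_temperature <= 0:
            raise ValueError("initial_temperature must be positive or 'auto'")


@dataclass(frozen=True)
class FitResult:
    """Best parameter set found, with bookkeeping.

    ``aicc`` is None (with a warning at fit time) when the small-sample
    correction is undefined, i.e. when S_C*S_R <= k + 1.
    """

    model_kind: str
    params: object
    log_l: float
    k: int
    aicc: float | None
    seed: int
    converged: bool
    trace: tuple = field(default=(), repr=False)


def _reflect(x: float, lo: float, hi: float) -> float:
    """Reflect a proposed value back into [lo, hi]."""
    width = hi - lo
    y = (x - lo) % (2.0 * width)
    return lo + (width - abs(y - width))


def _restart_rng(seed: int, restart: int) -> np.random.Generator:
    """Deterministic per-restart stream; restart k is the same whether run
    alone or as part of a multi-restart fit."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(restart,)))


# ---------------------------------------------------------------------------
# BPNM annealing with incremental row/column updates

def _bpnm_cell_ll(a_slice: np.ndarray, p_slice: np.ndarray) -> np.ndarray:
    return np.where(a_slice == 1, np.log(p_slice), np.log1p(-p_slice))


def _bpnm_matrix(n, c, r, g, p_max) -> np.ndarray:
    z = np.abs(n[:, None] - c[None, :]) / (r[None, :] / 2.0)
    return np.clip(p_max * np.exp(-(z ** g)), EPS, 1.0 - EPS)


def _propose(value: float, lo: float, hi: float, sd: float, rng) -> float:
    """Local Gaussian step, or (with small probability) a uniform redraw.

    The long-range component matters: the likelihood over axis orderings
    is multimodal, and a resource stuck on the wrong side of the axis can
    only reach its slot by a jump once the temperature is low.
    """
    if rng.random() < _P_JUMP:
        return rng.uniform(lo, hi)
    return _reflect(value + rng.normal(0.0, sd), lo, hi)


def _spectral_init(a: np.ndarray, rng: np.random.Generator):
    """Seriation start: order resources by the first principal component of
    their consumption profiles, then place consumers at the mean position
    of their diet with width set by the diet's span.

    The leading singular vector of the centered adjacency recovers the
    latent axis ordering up to reflection when diets are contiguous, which
    drops the annealer into the correct ordering basin.
    """
    x = a - a.mean(axis=1, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    order = np.argsort(u[:, 0] * s[0], kind="stable")
    s_r, s_c = a.shape
    n = np.empty(s_r)
    n[order] = (np.arange(s_r) + 0.5) / s_r
    c = np.empty(s_c)
    r = np.empty(s_c)
    for i in range(s_c):
        diet = np.nonzero(a[:, i])[0]
        if len(diet):
            c[i] = n[diet].mean()
            span = n[diet].max() - n[diet].min() if len(diet) > 1 else 0.0
            r[i] = max(1.2 * span, 0.1)
        else:
            c[i], r[i] = rng.uniform(), 0.3
    return n, c, np.clip(r, _R_MIN, R_CAP)


def _anneal_bpnm(net, cfg: AnnealConfig, rng: np.random.Generator, informed: bool = False):
    a = net.adjacency
    s_r, s_c = a.shape
    if informed:
        n, c, r = _spectral_init(a.astype(float), rng)
    else:
        n = rng.uniform(0.0, 1.0, s_r)
        c = rng.uniform(0.0, 1.0, s_c)
        r = np.full(s_c, 0.3)
    g = cfg.fix_g if cfg.fix_g is not None else 2.0
    p_max = cfg.fix_p_max if cfg.fix_p_max is not None else 0.9

    ll_cells = _bpnm_cell_ll(a, _bpnm_matrix(n, c, r, g, p_max))
    cur_ll = float(ll_cells.sum())

    # an informed start would be destroyed by the high auto temperature;
    # quench it gently instead
    if informed and cfg.initial_temperature == "auto":
        t0 = 1.0
    else:
        t0 = _initial_temperature(cfg, lambda q: _probe_ll_bpnm(net, q), rng)
    best = (cur_ll, n.copy(), c.copy(), r.copy(), g, p_max)
    trace, best_history = [], []
    sd = cfg.proposal_sd

    def sweep_once(temp: float) -> None:
        nonlocal cur_ll, g, p_max, ll_cells, n, c
        # resource positions: row updates
        for j in range(s_r):
            new = _propose(n[j], 0.0, 1.0, sd, rng)
            z = np.abs(new - c) / (r / 2.0)
            p_row = np.clip(p_max * np.exp(-(z ** g)), EPS, 1.0 - EPS)
            row_ll = _bpnm_cell_ll(a[j], p_row)
            delta = float(row_ll.sum() - ll_cells[j].sum())
            if delta > 0 or (temp > 0 and rng.random() < math.exp(min(delta / temp, 0.0))):
                n[j] = new
                ll_cells[j] = row_ll
                cur_ll += delta
        # consumer centers and widths: column updates
        for arr, lo, hi in ((c, 0.0, 1.0), (r, _R_MIN, R_CAP)):
            for i in range(s_c):
                old = arr[i]
                arr[i] = _propose(old, lo, hi, sd, rng)
                z = np.abs(n - c[i]) / (r[i] / 2.0)
                p_col = np.clip(p_max * np.exp(-(z ** g)), EPS, 1.0 - EPS)
                col_ll = _bpnm_cell_ll(a[:, i], p_col)
                delta = float(col_ll.sum() - ll_cells[:, i].sum())
                if delta > 0 or (temp > 0 and rng.random() < math.exp(min(delta / temp, 0.0))):
                    ll_cells[:, i] = col_ll
                    cur_ll += delta
                else:
                    arr[i] = old
        # niche-edge moves: perturb one edge of a consumer's interval
        # (c -+ r/2) while the other stays put; c and r moves alone couple
        # the two edges and mix poorly
        for i in range(s_c):
            lo_e, hi_e = c[i] - r[i] / 2.0, c[i] + r[i] / 2.0
            if rng.random() < 0.5:
                lo_e = lo_e + rng.normal(0.0, sd)
            else:
                hi_e = hi_e + rng.normal(0.0, sd)
            if hi_e - lo_e < _R_MIN or hi_e - lo_e > R_CAP:
                continue
            c_new, r_new = (lo_e + hi_e) / 2.0, hi_e - lo_e
            if not (0.0 <= c_new <= 1.0):
                continue
            z = np.abs(n - c_new) / (r_new / 2.0)
            p_col = np.clip(p_max * np.exp(-(z ** g)), EPS, 1.0 - EPS)
            col_ll = _bpnm_cell_ll(a[:, i], p_col)
            delta = float(col_ll.sum() - ll_cells[:, i].sum())
            if delta > 0 or (temp > 0 and rng.random() < math.exp(min(delta / temp, 0.0))):
                c[i], r[i] = c_new, r_new
                ll_cells[:, i] = col_ll
                cur_ll += delta
        # ordering moves: axis structure is only weakly explored by local
        # steps, so propose position swaps and segment reversals directly
        for _ in range(s_r):
            j, k = rng.integers(0, s_r, 2)
            if j == k:
                continue
            n_j, n_k = n[k], n[j]
            z = np.abs(np.array([[n_j], [n_k]]) - c[None, :]) / (r[None, :] / 2.0)
            p_rows = np.clip(p_max * np.exp(-(z ** g)), EPS, 1.0 - EPS)
            rows_ll = _bpnm_cell_ll(a[[j, k]], p_rows)
            delta = float(rows_ll.sum() - ll_cells[[j, k]].sum())
            if delta > 0 or (temp > 0 and rng.random() < math.exp(min(delta / temp, 0.0))):
                n[j], n[k] = n_j, n_k
                ll_cells[[j, k]] = rows_ll
                cur_ll += delta
        for _ in range(s_c):
            i, l = rng.integers(0, s_c, 2)
            if i == l:
                continue
            c_pair = np.array([c[l], c[i]])
            r_pair = np.array([r[l], r[i]])
            z = np.abs(n[:, None] - c_pair[None, :]) / (r_pair[None, :] / 2.0)
            p_cols = np.clip(p_max * np.exp(-(z ** g)), EPS, 1.0 - EPS)
            cols_ll = _bpnm_cell_ll(a[:, [i, l]], p_cols)
            delta = float(cols_ll.sum() - ll_cells[:, [i, l]].sum())
            if delta > 0 or (temp > 0 and rng.random() < math.exp(min(delta / temp, 0.0))):
                c[i], c[l] = c_pair
                r[i], r[l] = r_pair
                ll_cells[:, [i, l]] = cols_ll
                cur_ll += delta
        for _ in range(2):  # window reflection: reverse one stretch of the axis
            x1, x2 = np.sort(rng.uniform(0.0, 1.0, 2))
            n_new = np.where((n >= x1) & (n <= x2), x1 + x2 - n, n)
            c_new = np.where((c >= x1) & (c <= x2), x1 + x2 - c, c)
            cells = _bpnm_cell_ll(a, _bpnm_matrix(n_new, c_new, r, g, p_max))
            delta = float(cells.sum() - cur_ll)
            if delta > 0 or (temp > 0 and rng.random() < math.exp(min(delta / temp, 0.0))):
                n, c = n_new, c_new
                ll_cells = cells
                cur_ll += delta
        # globals: g on log scale, p_max on logit scale; full recompute
        for which in ("g", "p_max"):
            if (which == "g" and cfg.fix_g is not None) or (
                    which == "p_max" and cfg.fix_p_max is not None):
                continue
            if which == "g":
                new_g = math.exp(_reflect(math.log(g) + rng.normal(0.0, sd),
                                          math.log(G_MIN), math.log(G_CAP)))
                cand = (new_g, p_max)
            else:
                logit = math.log(p_max / (1.0 - p_max))
                new_p = 1.0 / (1.0 + math.exp(-(logit + rng.normal(0.0, sd))))
                cand = (g, min(max(new_p, EPS * 2), 1.0 - EPS))
            cells = _bpnm_cell_ll(a, _bpnm_matrix(n, c, r, *cand))
            delta = float(cells.sum() - cur_ll)
            if delta > 0 or (temp > 0 and rng.random() < math.exp(min(delta / temp, 0.0))):
                g, p_max = cand
                ll_cells = cells
                cur_ll += delta

    for sweep in range(cfg.n_sweeps):
        temp = t0 * cfg.cooling_factor ** sweep
        sweep_once(temp)
        if cur_ll > best[0]:
            best = (cur_ll, n.copy(), c.copy(), r.copy(), g, p_max)
        trace.append((sweep, temp, cur_ll))
        best_history.append(best[0])

    # zero-temperature polish from the best visited state; alternating step
    # sizes let both coarse and fine refinements land
    cur_ll, n, c, r, g, p_max = best[0], best[1].copy(), best[2].copy(), best[3].copy(), best[4], best[5]
    ll_cells = _bpnm_cell_ll(a, _bpnm_matrix(n, c, r, g, p_max))
    base_sd, stagnant = sd, 0
    for extra in range(_POLISH_SWEEPS):
        before = cur_ll
        sd = base_sd if extra % 2 == 0 else base_sd / 2.5
        sweep_once(0.0)
        if cur_ll > best[0]:
            best = (cur_ll, n.copy(), c.copy(), r.copy(), g, p_max)
        best_history.append(best[0])
        stagnant = stagnant + 1 if cur_ll - before < 1e-6 else 0
        if stagnant >= _POLISH_PATIENCE:
            break
    sd = base_sd

    params = BPNMParams(best[1], best[2], best[3], best[4], best[5])
    return best[0], params, trace, best_history


def _probe_ll_bpnm(net, rng) -> float:
    s_r, s_c = net.adjacency.shape
    params = BPNMParams(rng.uniform(0, 1, s_r), rng.uniform(0, 1, s_c),
                        rng.uniform(0.05, R_CAP, s_c), 2.0, 0.9)
    return log_likelihood(net, probability_matrix(params, net))


# ---------------------------------------------------------------------------
# cascade annealing (count-based likelihood)

def _cascade_ll_from_counts(l_allowed_obs: int, l_p: int, l_total: int, n_cells: int) -> float:
    """Likelihood of the cascade given only the allowed-pair counts."""
    p_a = min(l_total / l_p, 1.0 - EPS)
    lf = l_total - l_allowed_obs          # observed links on forbidden pairs
    nf = n_cells - l_p
    return (l_allowed_obs * math.log(p_a) + (l_p - l_allowed_obs) * math.log1p(-p_a)
            + lf * math.log(EPS) + (nf - lf) * math.log1p(-EPS))


def _anneal_cascade(net, cfg: AnnealConfig, rng: np.random.Generator):
    a = net.adjacency
    s_r, s_c = a.shape
    n_cells = s_r * s_c
    l_total = net.n_links
    phi = rng.uniform(0, 1, s_c)
    psi = rng.uniform(0, 1, s_r)

    allowed = psi[:, None] < phi[None, :]
    l_p = int(allowed.sum())
    l_in = int((a & allowed).sum())
    cur_ll = _cascade_ll_from_counts(l_in, l_p, l_total, n_cells) if l_p else -math.inf

    t0 = _initial_temperature(cfg, lambda q: _probe_ll_cascade(net, q), rng)
    best = (cur_ll, phi.copy(), psi.copy())
    trace, best_history = [], []
    sd = cfg.proposal_sd

    def sweep_once(temp: float) -> None:
        nonlocal cur_ll, l_p, l_in
        for side, arr in (("phi", phi), ("psi", psi)):
            for i in range(len(arr)):
                new = _propose(arr[i], 0.0, 1.0, sd, rng)
                if side == "phi":
                    col_new = psi < new
                    d_lp = int(col_new.sum()) - int(allowed[:, i].sum())
                    d_lin = int((a[:, i] & col_new).sum()) - int((a[:, i] & allowed[:, i]).sum())
                else:
                    row_new = new < phi
                    d_lp = int(row_new.sum()) - int(allowed[i].sum())
                    d_lin = int((a[i] & row_new).sum()) - int((a[i] & allowed[i]).sum())
                if l_p + d_lp == 0:
                    continue
                new_ll = _cascade_ll_from_counts(l_in + d_lin, l_p + d_lp, l_total, n_cells)
                delta = new_ll - cur_ll
                if delta > 0 or (temp > 0 and rng.random() < math.exp(min(delta / temp, 0.0))):
                    arr[i] = new
                    if side == "phi":
                        allowed[:, i] = col_new
                    else:
                        allowed[i] = row_new
                    l_p += d_lp
                    l_in += d_lin
                    cur_ll = new_ll

    for sweep in range(cfg.n_sweeps):
        temp = t0 * cfg.cooling_factor ** sweep
        sweep_once(temp)
        if cur_ll > best[0]:
            best = (cur_ll, phi.copy(), psi.copy())
        trace.append((sweep, temp, cur_ll))
        best_history.append(best[0])

    # zero-temperature polish from the best visited state
    phi, psi = best[1].copy(), best[2].copy()
    allowed = psi[:, None] < phi[None, :]
    l_p = int(allowed.sum())
    l_in = int((a & allowed).sum())
    cur_ll = best[0]
    stagnant = 0
    for extra in range(_POLISH_SWEEPS):
        before = cur_ll
        sweep_once(0.0)
        if cur_ll > best[0]:
            best = (cur_ll, phi.copy(), psi.copy())
        best_history.append(best[0])
        stagnant = stagnant + 1 if cur_ll - before < 1e-6 else 0
        if stagnant >= _POLISH_PATIENCE:
            break

    return best[0], CascadeParams(best[1], best[2]), trace, best_history


def _probe_ll_cascade(net, rng) -> float:
    s_r, s_c = net.adjacency.shape
    phi = rng.uniform(0, 1, s_c)
    psi = rng.uniform(0, 1, s_r)
    allowed = psi[:, None] < phi[None, :]
    l_p = int(allowed.sum())
    if l_p == 0:
        return -1e6
    l_in = int((net.adjacency & allowed).sum())
    return _cascade_ll_from_counts(l_in, l_p, net.n_links, s_r * s_c)


def _initial_temperature(cfg: AnnealConfig, probe, rng) -> float:
    if cfg.initial_temperature != "auto":
        return float(cfg.initial_temperature)
    probes = [probe(rng) for _ in range(50)]
    sd = float(np.std(probes))
    return sd if sd > 0 else 1.0


# ---------------------------------------------------------------------------
# public interface

def fit_model(net, model_kind: str, config: AnnealConfig | None = None) -> FitResult:
    """Fit one model to a network and return the best-of-restarts result.

    Deterministic given ``config.seed``; the random model returns its
    closed-form maximum-likelihood estimate directly.
    """
    config = config or AnnealConfig()
    if net.n_links < 1:
        raise ValueError("cannot fit a network with zero links")
    s_r, s_c = net.adjacency.shape
    k = parameter_count(model_kind, s_c, s_r)
    n_obs = s_r * s_c

    if model_kind == "random":
        p_hat = min(max(net.n_links / n_obs, EPS), 1.0 - EPS)
        params = RandomParams(p_hat)
        log_l = log_likelihood(net, probability_matrix(params, net))
        trace, converged = (), True
    else:
        best = None
        for restart in range(config.n_restarts):
            rng = _restart_rng(config.seed, restart)
            if model_kind == "bpnm":
                # first two restarts start from a spectral seriation of the
                # matrix; the rest are independent uniform starts
                log_l_r, params_r, trace_r, hist = _anneal_bpnm(
                    net, config, rng, informed=(restart < 2))
            else:
                log_l_r, params_r, trace_r, hist = _anneal_cascade(net, config, rng)
            if best is None or log_l_r > best[0]:
                best = (log_l_r, params_r, trace_r, hist)
        log_l, params, trace_list, hist = best
        tail = max(1, int(0.1 * config.n_sweeps))
        converged = (hist[-1] - hist[-tail]) < 1e-6
        trace = tuple(trace_list)
        # invariant: stored logL is the recomputed likelihood of the stored params
        log_l = log_likelihood(net, probability_matrix(params, net))

    try:
        crit = aicc(log_l, k, n_obs)
    except ValueError:
        warnings.warn(
            f"AICc undefined for {model_kind} (n_obs={n_obs} <= k+1={k + 1}); "
            "model excluded from AICc comparison", stacklevel=2)
        crit = None
    return FitResult(model_kind, params, log_l, k, crit, config.seed, converged, trace)


def compare_models(net, kinds=("bpnm", "cascade", "random"),
                   config: AnnealConfig | None = None) -> pd.DataFrame:
    """Fit several models and rank them by AICc (ascending; lower is better).

    The ``aicc_ratio_bpnm`` column reports AICc(BPNM) / AICc(model), the
    relative-performance axis used for model-selection plots.  Per-model
    failures are recorded as NaN rows rather than aborting the comparison.
    """
    if len(kinds) < 2:
        raise ValueError("need at least two model kinds to compare")
    rows, fits = [], {}
    for kind in kinds:
        try:
            fit = fit_model(net, kind, config)
            fits[kind] = fit
            rows.append({"model_kind": kind, "log_l": fit.log_l, "k": fit.k,
                         "aicc": np.nan if fit.aicc is None else fit.aicc})
        except Exception as exc:  # noqa: BLE001 — propagate per-kind, keep others
            rows.append({"model_kind": kind, "log_l": np.nan, "k": np.nan,
                         "aicc": np.nan, "error": str(exc)})
    table = pd.DataFrame(rows).sort_values("aicc", na_position="last").reset_index(drop=True)
    bpnm_aicc = table.loc[table.model_kind == "bpnm", "aicc"]
    if len(bpnm_aicc) and np.isfinite(bpnm_aicc.iloc[0]):
        table["aicc_ratio_bpnm"] = bpnm_aicc.iloc[0] / table["aicc"]
    table.attrs["fits"] = fits
    return table


def sensitivity_profile(net, fit: FitResult, species_side: str, species_index: int,
                        param_name: str, half_range: float = 0.3,
                        step: float = 0.01) -> list[tuple[float, float]]:
    """Likelihood profile around the ML value of one niche parameter.

    Perturbs a single parameter of the fitted BPNM over offsets
    ``-half_range .. +half_range`` while all other parameters stay at
    their ML values; offsets that would leave the legal domain are
    truncated, so profiles of parameters near a bound are asymmetric.
    """
    if not isinstance(fit.params, BPNMParams):
        raise ValueError("sensitivity profiles are defined for BPNM fits")
    params = fit.params
    if species_side == "resource":
        if param_name != "n":
            raise ValueError("resource species carry only the position parameter n")
        base, lo, hi = params.n[species_index], 0.0, 1.0
    elif species_side == "consumer":
        if param_name == "c":
            base, lo, hi = params.c[species_index], 0.0, 1.0
        elif param_name == "r":
            base, lo, hi = params.r[species_index], _R_MIN, R_CAP
        else:
            raise ValueError("consumer parameters are c and r")
    else:
        raise ValueError("species_side must be 'consumer' or 'resource'")

    n_steps = int(round(half_range / step))
    profile = []
    for kk in range(-n_steps, n_steps + 1):
        offset = kk * step
        value = base + offset
        if value < lo or value > hi:
            continue
        if species_side == "resource":
            n_vec = params.n.copy(); n_vec[species_index] = value
            pert = replace(params, n=n_vec)
        elif param_name == "c":
            c_vec = params.c.copy(); c_vec[species_index] = value
            pert = replace(params, c=c_vec)
        else:
            r_vec = params.r.copy(); r_vec[species_index] = value
            pert = replace(params, r=r_vec)
        profile.append((offset, log_likelihood(net, probability_matrix(pert, net))))
    return profile
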