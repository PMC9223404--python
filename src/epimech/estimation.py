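"""Force-balance parameter estimation, AIC model selection and uncertainty.

The method treats epithelial morphogenesis as quasi-static: at every
three-way cell vertex the junction tensions and cell pressures balance,
F = C X ~ 0, where C holds purely geometric coefficients (unit vectors
along junctions for tensions; half cross-differences of flanking loop
vertices for pressures) and X stacks the unknown tensions and pressures.
Substituting a candidate mechanical model T = L_T beta_T, P = L_P beta_P
turns the balance into a linear regression F = C L beta = 0 in the model
coefficients. The overall force scale is not identifiable, so the base line
tension lambda0 is fixed at 1 and the remaining coefficients minimize
||F||^2. Candidate models of different complexity are compared by

    AIC = n log(2 pi sigma^2) + n + 2 (p + 1),   sigma^2 = F'F / n,

with p the number of free coefficients. Only vertices whose complete
neighborhoods survive preprocessing (short-junction and giant-cell
exclusion) contribute equations, so every retained equation is physically
complete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import (
    ConfigurationError,
    DegenerateGeometryError,
    DegenerateScaleError,
    DomainError,
    EmptySystemError,
    PerfectFitError,
)
from .mesh import Tissue, classify_vertices
from .models import (
    ANISO_SPRING,
    CONVENTIONAL,
    LinearCoefficients,
    ModelSpec,
    ParameterSet,
    pressure_features,
    tension_features,
    to_polar,
    _polar_pair,
)

__all__ = [
    "PreprocessConfig",
    "ExclusionReport",
    "BalanceSystem",
    "FitResult",
    "AnisotropyResult",
    "preprocess",
    "assemble_balance_system",
    "fit",
    "aic",
    "model_select",
    "tension_anisotropy",
    "standard_errors",
    "normalize_estimates",
    "estimate",
    "recovered_parameters",
]

_MU1_CAP = 1.0 - 1e-6


@dataclass
class PreprocessConfig:
    """Exclusion thresholds and normalization switch.

    min_junction_length is in the tissue's raw coordinate units: 3 pixels is
    the convention for segmented data, 0.05 * sqrt(A0) for simulated data.
    Cells larger than max_cell_area_factor times the median area are
    excluded (outliers such as sensory cells). When normalize is set the
    coordinates are divided by sqrt(median cell area) so the median area
    becomes one.
    """

    min_junction_length: float = 0.05
    max_cell_area_factor: float = 2.0
    normalize: bool = True

    def __post_init__(self):
        if self.min_junction_length < 0 or self.max_cell_area_factor <= 0:
            raise ConfigurationError("preprocess thresholds must be positive")


@dataclass
class ExclusionReport:
    excluded_junctions: set[int]
    excluded_cells: set[int]
    median_area: float
    scale: float  # sqrt(median_area); 1.0 if not normalized
    n_junctions_total: int = 0
    n_cells_total: int = 0


@dataclass
class BalanceSystem:
    """Assembled force-balance matrices and their index maps."""

    C: np.ndarray          # n x m geometric coefficients
    L_T: np.ndarray        # K_j x q_T tension features
    L_P: np.ndarray        # K_c x 1 pressure features
    M: np.ndarray          # C @ blockdiag(L_T, L_P), n x (q_T + 1)
    row_vertices: list[int]        # vertex id per row pair (x row = 2i, y row = 2i+1)
    junction_ids: list[int]        # column order of the tension block
    cell_ids: list[int]            # column order of the pressure block
    lengths: np.ndarray
    angles: np.ndarray
    areas: np.ndarray
    spec: ModelSpec

    @property
    def n(self) -> int:
        return self.C.shape[0]

    @property
    def m(self) -> int:
        return self.C.shape[1]


@dataclass
class FitResult:
    spec: ModelSpec
    coefficients: dict[str, float]      # includes the fixed scale and k
    params: ParameterSet                # polar form
    residual: np.ndarray
    sigma2: float
    aic: float
    n: int
    p: int
    predicted_tensions: dict[int, float]
    predicted_pressures: dict[int, float]
    standard_errors: dict[str, float] | None = None
    constrained: bool = False
    boundary_flag: bool = False
    perfect_fit: bool = False
    system: BalanceSystem | None = field(default=None, repr=False)


@dataclass
class AnisotropyResult:
    R_T: float
    Theta: float


# ------------------------------------------------------------- preprocessing

def preprocess(tissue: Tissue, config: PreprocessConfig) -> tuple[Tissue, ExclusionReport]:
    """Mark outlier junctions/cells and normalize the spatial scale.

    Junctions shorter than the threshold (their angle is unreliable) and
    cells larger than twice the median area are marked excluded; thresholds
    apply on the raw scale. The returned tissue keeps the full geometry with
    coordinates divided by sqrt(median cell area) when normalization is on.
    """
    if not tissue.cells:
        raise EmptySystemError("tissue has no cells")
    lengths = {jid: tissue.junction_length(jid) for jid in tissue.junctions}
    excluded_j = {jid for jid, l in lengths.items() if l < config.min_junction_length}
    if len(excluded_j) == len(tissue.junctions):
        raise EmptySystemError("all junctions excluded by the length threshold")
    areas = {cid: tissue.cell_area(cid) for cid in tissue.cells}
    med = float(np.median(list(areas.values())))
    excluded_c = {cid for cid, a in areas.items()
                  if a > config.max_cell_area_factor * med}
    scale = math.sqrt(med) if config.normalize else 1.0
    out = tissue.scaled(1.0 / scale) if config.normalize else tissue.copy()
    report = ExclusionReport(
        excluded_junctions=excluded_j,
        excluded_cells=excluded_c,
        median_area=med,
        scale=scale,
        n_junctions_total=len(tissue.junctions),
        n_cells_total=len(tissue.cells),
    )
    return out, report


# ------------------------------------------------------------------ assembly

def assemble_balance_system(
    tissue: Tissue,
    spec: ModelSpec,
    exclusions: ExclusionReport | None = None,
) -> BalanceSystem:
    """Build C, the feature matrices and the design matrix M = C L.

    Equations (two rows) are written only for vertices that are interior,
    not frame-flagged, and whose every incident junction and adjacent cell
    survived preprocessing.
    """
    excl_j = exclusions.excluded_junctions if exclusions else set()
    excl_c = exclusions.excluded_cells if exclusions else set()

    junction_ids = [j for j in sorted(tissue.junctions) if j not in excl_j]
    cell_ids = [c for c in sorted(tissue.cells) if c not in excl_c]
    jcol = {j: i for i, j in enumerate(junction_ids)}
    ccol = {c: len(junction_ids) + i for i, c in enumerate(cell_ids)}

    # vertex -> cells whose loop contains it, with flanking loop neighbors
    vertex_cells: dict[int, list[tuple[int, int, int]]] = {}
    for cid in sorted(tissue.cells):
        loop = tissue.cells[cid].vertex_loop
        n = len(loop)
        for i, v in enumerate(loop):
            vertex_cells.setdefault(v, []).append(
                (cid, loop[i - 1], loop[(i + 1) % n])
            )

    kind = classify_vertices(tissue)
    rows: list[int] = []
    for vid in sorted(tissue.vertices):
        if kind[vid] != "interior" or tissue.vertices[vid].frame_boundary:
            continue
        jids = tissue.vertex_junctions[vid]
        if any(j in excl_j for j in jids):
            continue
        if any(cid in excl_c for cid, _, _ in vertex_cells.get(vid, [])):
            continue
        rows.append(vid)
    if not rows:
        raise EmptySystemError("no usable interior vertices after preprocessing")

    n = 2 * len(rows)
    m = len(junction_ids) + len(cell_ids)
    C = np.zeros((n, m))
    for r, vid in enumerate(rows):
        x0, y0 = tissue.vertices[vid].x, tissue.vertices[vid].y
        for jid in tissue.vertex_junctions[vid]:
            j = tissue.junctions[jid]
            far = j.v2 if j.v1 == vid else j.v1
            fx, fy = tissue.vertices[far].x, tissue.vertices[far].y
            l = math.hypot(fx - x0, fy - y0)
            C[2 * r, jcol[jid]] = (fx - x0) / l
            C[2 * r + 1, jcol[jid]] = (fy - y0) / l
        for cid, vprev, vnext in vertex_cells.get(vid, []):
            pu, pw = tissue.vertices[vprev], tissue.vertices[vnext]
            C[2 * r, ccol[cid]] = 0.5 * (pw.y - pu.y)
            C[2 * r + 1, ccol[cid]] = -0.5 * (pw.x - pu.x)

    lengths = np.array([tissue.junction_length(j) for j in junction_ids])
    angles = np.array([tissue.junction_angle(j) for j in junction_ids])
    areas = np.array([tissue.cell_area(c) for c in cell_ids])
    if spec.family == CONVENTIONAL:
        perim = {c: tissue.cell_perimeter(c) for c in tissue.cells}
        L_sum = np.array([
            sum(perim[c] for c in tissue.junctions[j].adjacent_cells)
            for j in junction_ids
        ])
        L_T = tension_features(spec, lengths, angles, L_sum)
    else:
        L_T = tension_features(spec, lengths, angles)
    L_P = pressure_features(spec, areas)
    M = np.hstack([
        C[:, : len(junction_ids)] @ L_T,
        C[:, len(junction_ids):] @ L_P,
    ])
    return BalanceSystem(C=C, L_T=L_T, L_P=L_P, M=M, row_vertices=rows,
                         junction_ids=junction_ids, cell_ids=cell_ids,
                         lengths=lengths, angles=angles, areas=areas, spec=spec)


# ----------------------------------------------------------------------- AIC

def aic(sigma2: float, n: int, p: int) -> float:
    """Akaike information criterion n log(2 pi sigma^2) + n + 2 (p + 1)."""
    if sigma2 == 0.0:
        raise PerfectFitError("zero residual variance; AIC is -infinity")
    if sigma2 < 0 or n < 1 or p < 0:
        raise DomainError("invalid AIC arguments")
    return n * math.log(2.0 * math.pi * sigma2) + n + 2.0 * (p + 1)


# ----------------------------------------------------------------------- fit

def _free_names(spec: ModelSpec) -> list[str]:
    return list(spec.tension_columns[1:]) + ["k"]


def _constrained_refit(y: np.ndarray, A: np.ndarray, spec: ModelSpec,
                       beta0: np.ndarray) -> tuple[np.ndarray, bool]:
    """Refit under the family's parameter constraints.

    Anisotropic spring family: lambda1 >= 0 and, when the anisotropy
    columns are present, sqrt(lambda1'^2 + lambda1''^2) <= (1 - 1e-6) *
    lambda1 (so mu1 < 1). Conventional family: Gamma0 >= 0. Returns
    (coefficients, at_boundary).
    """
    names = _free_names(spec)

    def obj(b):
        r = y + A @ b
        return float(r @ r)

    def grad(b):
        return 2.0 * A.T @ (y + A @ b)

    cons = []
    bounds = [(None, None)] * len(names)
    if spec.family == ANISO_SPRING and "lambda1" in names:
        i1 = names.index("lambda1")
        bounds[i1] = (0.0, None)
        if "lambda1_s" in names:
            js, jc = names.index("lambda1_s"), names.index("lambda1_c")
            cons.append({
                "type": "ineq",
                "fun": lambda b: (_MU1_CAP * b[i1]) ** 2 - b[js] ** 2 - b[jc] ** 2,
            })
    if spec.family == CONVENTIONAL and "Gamma0" in names:
        ig = names.index("Gamma0")
        bounds[ig] = (0.0, None)

    x0 = beta0.copy()
    # project the start into the feasible region
    if spec.family == ANISO_SPRING and "lambda1" in names:
        i1 = names.index("lambda1")
        x0[i1] = max(x0[i1], 1e-8)
        if "lambda1_s" in names:
            js, jc = names.index("lambda1_s"), names.index("lambda1_c")
            r = math.hypot(x0[js], x0[jc])
            cap = _MU1_CAP * x0[i1]
            if r > cap and r > 0:
                x0[js] *= cap / r
                x0[jc] *= cap / r
    if spec.family == CONVENTIONAL:
        ig = names.index("Gamma0")
        x0[ig] = max(x0[ig], 1e-8)

    res = optimize.minimize(obj, x0, jac=grad, bounds=bounds, constraints=cons,
                            method="SLSQP",
                            options={"maxiter": 500, "ftol": 1e-14})
    beta = res.x
    at_boundary = False
    if spec.family == ANISO_SPRING and "lambda1" in names:
        i1 = names.index("lambda1")
        if beta[i1] <= 1e-7:
            at_boundary = True
        if "lambda1_s" in names:
            r = math.hypot(beta[names.index("lambda1_s")], beta[names.index("lambda1_c")])
            if r >= _MU1_CAP * beta[i1] * (1 - 1e-6):
                at_boundary = True
    if spec.family == CONVENTIONAL and beta[names.index("Gamma0")] <= 1e-7:
        at_boundary = True
    return beta, at_boundary


def _violates_constraints(spec: ModelSpec, beta: np.ndarray) -> bool:
    names = _free_names(spec)
    if spec.family == ANISO_SPRING and "lambda1" in names:
        lam1 = beta[names.index("lambda1")]
        if lam1 <= 0:
            return True
        if "lambda1_s" in names:
            r = math.hypot(beta[names.index("lambda1_s")],
                           beta[names.index("lambda1_c")])
            if r >= lam1:  # mu1 >= 1
                return True
    if spec.family == CONVENTIONAL:
        if beta[names.index("Gamma0")] <= 0:
            return True
    return False


def fit(tissue: Tissue, spec: ModelSpec,
        exclusions: ExclusionReport | None = None,
        system: BalanceSystem | None = None) -> FitResult:
    """Least-squares fit of one model with the scale fixed at lambda0 = 1.

    The tissue is expected to be preprocessed (see :func:`preprocess`); pass
    the exclusion report so incomplete equations are dropped. The first
    design column (the fixed-scale coefficient) becomes the regression
    target: minimize ||c0 + M' beta'||^2 over the free coefficients.
    """
    if system is None:
        system = assemble_balance_system(tissue, spec, exclusions)
    M = system.M
    y = M[:, 0]
    A = M[:, 1:]
    p = A.shape[1]
    if p > 0:
        rank = np.linalg.matrix_rank(A, tol=None)
        if rank < p:
            raise DegenerateGeometryError(
                f"design matrix rank {rank} < {p}: cell geometry too regular "
                "to identify the parameters (e.g. a regular hexagonal pattern)"
            )
        beta, *_ = np.linalg.lstsq(A, -y, rcond=None)
    else:
        beta = np.zeros(0)

    constrained = False
    at_boundary = False
    if _violates_constraints(spec, beta):
        beta, at_boundary = _constrained_refit(y, A, spec, beta)
        constrained = True

    F = y + A @ beta if p else y
    n = system.n
    sigma2 = float(F @ F) / n
    perfect = sigma2 == 0.0
    aic_value = -math.inf if perfect else aic(sigma2, n, spec.n_free_parameters)

    names = _free_names(spec)
    coefficients = {spec.tension_columns[0]: 1.0}
    coefficients.update(dict(zip(names, map(float, beta))))

    k_hat = coefficients["k"]
    tension_coeffs = {c: coefficients[c] for c in spec.tension_columns}
    try:
        params = to_polar(LinearCoefficients(spec, tension_coeffs, k_hat))
    except DegenerateScaleError:
        # spring constant / cortical elasticity pinned at zero by the
        # constraint: the anisotropy of an absent term is undefined, so it
        # is reported as zero
        base = spec.tension_columns[0]
        mu0, phi0 = _polar_pair(1.0, tension_coeffs.get(f"{base}_s", 0.0),
                                tension_coeffs.get(f"{base}_c", 0.0))
        if spec.family == ANISO_SPRING:
            params = ParameterSet(lambda0=1.0, mu0=mu0, phi0=phi0,
                                  lambda1=max(tension_coeffs.get("lambda1", 0.0), 0.0),
                                  k=k_hat)
        else:
            params = ParameterSet(lambda0=1.0, mu0=mu0, phi0=phi0,
                                  Gamma0=max(tension_coeffs.get("Gamma0", 0.0), 0.0),
                                  k=k_hat)

    beta_T = np.array([coefficients[c] for c in spec.tension_columns])
    That = system.L_T @ beta_T
    Phat = system.L_P[:, 0] * k_hat
    result = FitResult(
        spec=spec,
        coefficients=coefficients,
        params=params,
        residual=F,
        sigma2=sigma2,
        aic=aic_value,
        n=n,
        p=spec.n_free_parameters,
        predicted_tensions=dict(zip(system.junction_ids, map(float, That))),
        predicted_pressures=dict(zip(system.cell_ids, map(float, Phat))),
        constrained=constrained,
        boundary_flag=at_boundary,
        perfect_fit=perfect,
        system=system,
    )
    if not constrained and p > 0 and not perfect:
        try:
            result.standard_errors = standard_errors(result, system)
        except DegenerateGeometryError:
            result.standard_errors = None
    return result


def estimate(tissue: Tissue, spec: ModelSpec,
             pre_config: PreprocessConfig | None = None
             ) -> tuple[FitResult, ExclusionReport]:
    """Convenience pipeline: preprocess then fit; returns (fit, report)."""
    cfg = pre_config if pre_config is not None else PreprocessConfig()
    pre, report = preprocess(tissue, cfg)
    return fit(pre, spec, exclusions=report), report


# ------------------------------------------------------------ model selection

def model_select(tissue: Tissue, specs: list[ModelSpec],
                 exclusions: ExclusionReport | None = None
                 ) -> tuple[ModelSpec, list[dict]]:
    """Fit every candidate and return the AIC argmin (ties -> fewer p)."""
    if not specs:
        raise ConfigurationError("need at least one candidate model")
    table = []
    for spec in specs:
        rec: dict = {"spec": spec, "label": spec.label}
        try:
            f = fit(tissue, spec, exclusions=exclusions)
            rec.update(fit=f, aic=f.aic, p=f.p, sigma2=f.sigma2)
        except Exception as exc:  # noqa: BLE001 - failures recorded per model
            rec.update(fit=None, aic=math.inf, p=spec.n_free_parameters,
                       error=str(exc))
        table.append(rec)
    ok = [r for r in table if r["fit"] is not None]
    if not ok:
        raise DegenerateGeometryError("all candidate fits failed")
    best = min(ok, key=lambda r: (r["aic"], r["p"]))
    return best["spec"], table


# --------------------------------------------------------- anisotropy summary

def tension_anisotropy(tensions, angles) -> AnisotropyResult:
    """Nematic anisotropy of predicted tensions.

    R_T <T> e^{2 i Theta} = <T e^{2 i theta}> - <T><e^{2 i theta}>; R_T is
    the normalized magnitude and Theta (folded to [0, pi)) the orientation.
    """
    T = np.asarray(tensions, dtype=float)
    th = np.asarray(angles, dtype=float)
    if T.size == 0:
        raise DomainError("no junctions")
    mean_T = T.mean()
    if mean_T == 0:
        raise DomainError("mean tension is zero")
    e = np.exp(2j * th)
    z = (T * e).mean() - mean_T * e.mean()
    R = float(abs(z) / mean_T)
    Theta = float(np.angle(z) / 2.0) % math.pi
    if R == 0.0:
        Theta = 0.0
    return AnisotropyResult(R_T=R, Theta=Theta)


# ------------------------------------------------------------ standard errors

def standard_errors(fit_result: FitResult, system: BalanceSystem,
                    A0: float = 1.0) -> dict[str, float]:
    """Coefficient and derived-parameter standard errors.

    Coefficient covariance is sigma^2 (M'M)^{-1} on the free columns;
    derived quantities (mu, phi, normalized lambdas) get first-order
    (delta-method) propagation. 95% intervals are +- 1.96 SE.
    """
    M = system.M
    A = M[:, 1:]
    names = _free_names(fit_result.spec)
    beta = np.array([fit_result.coefficients[c] for c in names])
    AtA = A.T @ A
    try:
        cov = fit_result.sigma2 * np.linalg.inv(AtA)
    except np.linalg.LinAlgError as exc:
        raise DegenerateGeometryError("singular normal matrix") from exc
    out = {c: float(math.sqrt(max(cov[i, i], 0.0)))
           for i, c in enumerate(names)}

    spec = fit_result.spec
    derived: list[tuple[str, callable]] = []

    def _maybe(base: str, scale_name: str | None):
        s, c = f"{base}_s", f"{base}_c"
        if s in names and c in names:
            i_s, i_c = names.index(s), names.index(c)
            if scale_name is None:
                def mu_f(b, i_s=i_s, i_c=i_c):
                    return math.hypot(b[i_s], b[i_c])
            else:
                i_l = names.index(scale_name)

                def mu_f(b, i_s=i_s, i_c=i_c, i_l=i_l):
                    return math.hypot(b[i_s], b[i_c]) / b[i_l]
            def phi_f(b, i_s=i_s, i_c=i_c):
                return 0.5 * math.atan2(b[i_s], b[i_c])
            tag = {"lambda0": "mu0", "lambda1": "mu1",
                   "Lambda0": "mu0", "Gamma": "muG"}[base]
            ptag = {"mu0": "phi0", "mu1": "phi1", "muG": "phiG"}[tag]
            derived.append((tag, mu_f))
            derived.append((ptag, phi_f))

    _maybe("lambda0", None)   # lambda0 fixed at 1
    _maybe("Lambda0", None)
    _maybe("lambda1", "lambda1")
    _maybe("Gamma", "Gamma0")
    ik = names.index("k")
    derived.append(("lambda0_norm",
                    lambda b, ik=ik: 1.0 / (b[ik] * A0 ** 1.5)))
    if "lambda1" in names:
        i1 = names.index("lambda1")
        derived.append(("lambda1_norm",
                        lambda b, i1=i1, ik=ik: b[i1] / (b[ik] * A0)))

    for name, g in derived:
        grad = np.zeros(len(names))
        for i in range(len(names)):
            h = 1e-7 * (1.0 + abs(beta[i]))
            bp, bm = beta.copy(), beta.copy()
            bp[i] += h
            bm[i] -= h
            try:
                grad[i] = (g(bp) - g(bm)) / (2 * h)
            except (ZeroDivisionError, ValueError):
                grad[i] = np.nan
        var = float(grad @ cov @ grad)
        out[name] = float(math.sqrt(var)) if var >= 0 else float("nan")
    return out


# --------------------------------------------------------------- normalization

def normalize_estimates(fit_result: FitResult, k_hat: float, A0: float) -> dict[str, float]:
    """Dimensionless parameter estimates: lambda0 / (k A0^1.5), lambda1 / (k A0).

    A0 must be expressed in the same (normalized) coordinate units as the
    fitted tissue; mu and phi pass through unchanged.
    """
    if k_hat <= 0:
        raise DomainError("k_hat must be positive")
    if A0 <= 0:
        raise DomainError("A0 must be positive")
    c = fit_result.coefficients
    p = fit_result.params
    lam0 = c.get("lambda0", c.get("Lambda0", 1.0))
    out = {
        "lambda0": lam0 / (k_hat * A0 ** 1.5),
        "mu0": p.mu0,
        "phi0": p.phi0,
    }
    if fit_result.spec.family == ANISO_SPRING:
        out["lambda1"] = c.get("lambda1", 0.0) / (k_hat * A0)
        out["mu1"] = p.mu1
        out["phi1"] = p.phi1
    else:
        out["Gamma0"] = c.get("Gamma0", 0.0) / (k_hat * A0)
        out["muG"] = p.muG
        out["phiG"] = p.phiG
    out["k_rel"] = k_hat * A0 ** 1.5  # reciprocal of normalized lambda0
    return out


def recovered_parameters(fit_result: FitResult, report: ExclusionReport,
                         A0_true: float) -> dict[str, float]:
    """Normalized estimates using the true target area mapped into the
    fit's coordinate frame (A0 / median raw area), which makes the result
    independent of the raw coordinate scale."""
    A0n = A0_true / report.median_area if report.scale != 1.0 else A0_true
    return normalize_estimates(fit_result, fit_result.coefficients["k"], A0n)
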