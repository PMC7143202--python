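"""Henderson mixed-model equations, REML variance components, PEV and accuracy.

Two animal models are supported for the calving-interval trait:

* primiparous — one record per cow:
  ``y = μ + HYS + country + b1·age + b2·age² + a + e``
* multiparous — repeated records, a repeatability model adding the fixed
  effect of parity and a random permanent-environment effect per cow:
  ``y = μ + HYS + country + parity + b1·age + b2·age² + a + pe + e``

The additive effect ``a`` has covariance ``K σa²`` where K is the pedigree A
(pedigree BLUP) or the single-step H (ssGBLUP); the solver only ever needs
K⁻¹.  Variance components are estimated by average-information REML with
EM-REML fallback steps, which keeps the restricted likelihood non-decreasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse as sp

from .pedigree import Pedigree, RelationshipMatrix

logger = logging.getLogger(__name__)


class ModelError(ValueError):
    pass


class EstimabilityError(ModelError):
    pass


@dataclass
class PhenotypeTable:
    """Trait records with fixed-effect codes and covariates.

    Columns: ``animal_id, y, herd, year, season, country, parity, age``
    (age = age at first calving in months).
    """

    table: pd.DataFrame

    REQUIRED = ("animal_id", "y", "herd", "year", "season", "country", "parity", "age")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ModelError(f"phenotype table missing columns {missing}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def y(self) -> np.ndarray:
        return self.table["y"].to_numpy(dtype=float)


@dataclass
class ModelSpec:
    """Which of the two animal models applies and which relationship inverse."""

    model_kind: str = "primiparous"  # or "multiparous"
    relationship: str = "H"  # "H" (ssGBLUP) or "A" (pedigree BLUP)
    use_age_covariates: bool = True

    def __post_init__(self) -> None:
        if self.model_kind not in ("primiparous", "multiparous"):
            raise ModelError(f"unknown model kind {self.model_kind!r}")
        if self.relationship not in ("H", "A"):
            raise ModelError(f"relationship must be 'H' or 'A', got {self.relationship!r}")

    @property
    def has_pe(self) -> bool:
        return self.model_kind == "multiparous"


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    sigma_pe2: float = 0.0
    standard_errors: dict | None = None
    converged: bool = True
    loglik_trajectory: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.sigma_a2, self.sigma_e2, self.sigma_pe2) < 0:
            raise ModelError("variance components must be non-negative")

    @property
    def heritability(self) -> float:
        tot = self.sigma_a2 + self.sigma_pe2 + self.sigma_e2
        return self.sigma_a2 / tot if tot > 0 else float("nan")

    @property
    def lambda_ratio(self) -> float:
        if self.sigma_a2 <= 0:
            raise ModelError("sigma_a2 must be positive to form the variance ratio")
        return self.sigma_e2 / self.sigma_a2


@dataclass
class DesignBundle:
    """y, X (fixed), Z_animal (records × pedigree animals), optional Z_pe."""

    y: np.ndarray
    X: np.ndarray
    Z_animal: sp.csr_matrix
    Z_pe: sp.csr_matrix | None
    animal_ids: np.ndarray          # pedigree order, length = Z_animal columns
    pe_ids: np.ndarray | None       # animals with repeated records
    fixed_names: list

    @property
    def n_records(self) -> int:
        return len(self.y)


@dataclass
class MMESolution:
    fixed_effects: pd.Series
    ebv: pd.Series                  # per pedigree animal
    pe: pd.Series | None
    pev: pd.Series | None
    reliability: pd.Series | None
    accuracy: pd.Series | None
    vc: VarianceComponents


def _dummies(codes: pd.Series, prefix: str) -> tuple[np.ndarray, list]:
    """Drop-first indicator coding for one fixed factor."""
    cats = pd.Categorical(codes)
    levels = list(cats.categories)
    mat = np.zeros((len(codes), max(len(levels) - 1, 0)))
    for j, lev in enumerate(levels[1:]):
        mat[:, j] = (cats == lev).astype(float)
    names = [f"{prefix}[{lev}]" for lev in levels[1:]]
    return mat, names


def build_design(pheno: PhenotypeTable, spec: ModelSpec, ped: Pedigree,
                 on_rank_deficiency: str = "error") -> DesignBundle:
    """Assemble y, X, Z_animal and (for the repeatability model) Z_pe.

    X uses reference-level (drop-first) constraints per factor; age covariates
    are centered before squaring.  Z_animal spans *all* pedigree animals
    (zero columns for non-phenotyped ones) so K⁻¹ plugs in directly.

    When factors are nested (e.g. herds within countries, so country is a
    linear function of the HYS cells) X is rank deficient after the
    reference-level constraints.  ``on_rank_deficiency='error'`` (default)
    raises naming the confounded factors; ``'drop'`` prunes redundant columns
    by pivoted QR — fitted values and random-effect solutions are unaffected,
    only the parametrization of the fixed part changes.
    """
    df = pheno.table
    if spec.model_kind == "primiparous":
        if df["animal_id"].duplicated().any():
            raise ModelError("primiparous model requires one record per animal")

    cols = [np.ones((len(df), 1))]
    names = ["intercept"]
    hys = df["herd"].astype(str) + ":" + df["year"].astype(str) + ":" + df["season"].astype(str)
    for series, prefix in ((hys, "hys"), (df["country"], "country")):
        mat, nm = _dummies(series, prefix)
        cols.append(mat)
        names.extend(nm)
    if spec.model_kind == "multiparous":
        mat, nm = _dummies(df["parity"], "parity")
        cols.append(mat)
        names.extend(nm)
    if spec.use_age_covariates:
        age_c = df["age"].to_numpy(dtype=float)
        age_c = age_c - age_c.mean()
        cols.append(age_c[:, None])
        cols.append((age_c**2)[:, None])
        names.extend(["age", "age_sq"])
    X = np.hstack(cols)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        if on_rank_deficiency == "drop":
            _, _, piv = la.qr(X, mode="economic", pivoting=True)
            keep = np.sort(piv[:rank])
            dropped = [names[j] for j in range(X.shape[1]) if j not in set(keep.tolist())]
            logger.info("dropped %d confounded fixed-effect columns: %s",
                        len(dropped), ", ".join(dropped))
            X = X[:, keep]
            names = [names[j] for j in keep]
        else:
            # name the factors involved in the dependency for the error message
            raise EstimabilityError(
                f"fixed-effect design is rank deficient (rank {rank} < {X.shape[1]} columns); "
                "confounded factors among: hys, country"
                + (", parity" if spec.model_kind == "multiparous" else "")
            )

    rec_animal = ped.index_of(df["animal_id"].tolist())
    n_rec = len(df)
    Z_animal = sp.csr_matrix(
        (np.ones(n_rec), (np.arange(n_rec), rec_animal)), shape=(n_rec, len(ped))
    )

    Z_pe = None
    pe_ids = None
    if spec.has_pe:
        pe_animals = df["animal_id"].unique()
        pe_pos = {a: i for i, a in enumerate(pe_animals)}
        cols_pe = np.array([pe_pos[a] for a in df["animal_id"]])
        Z_pe = sp.csr_matrix(
            (np.ones(n_rec), (np.arange(n_rec), cols_pe)), shape=(n_rec, len(pe_animals))
        )
        pe_ids = np.asarray(pe_animals)

    return DesignBundle(
        y=df["y"].to_numpy(dtype=float),
        X=X,
        Z_animal=Z_animal,
        Z_pe=Z_pe,
        animal_ids=ped.ids,
        pe_ids=pe_ids,
        fixed_names=names,
    )


def _assemble_mme(design: DesignBundle, K_inv: np.ndarray, vc: VarianceComponents,
                  scale: str = "ratio") -> tuple[np.ndarray, np.ndarray]:
    """Coefficient matrix and RHS of the MME.

    ``scale='ratio'`` builds the classic form with K⁻¹·σe²/σa² (RHS = W′y);
    ``scale='rinv'`` divides data blocks by σe² so C⁻¹ is directly the
    sampling covariance of the solutions (used by REML and PEV).
    """
    X, Za, Zp = design.X, design.Z_animal, design.Z_pe
    y = design.y
    p = X.shape[1]
    qa = Za.shape[1]
    blocks = [X, Za.toarray()]
    if Zp is not None:
        if vc.sigma_pe2 <= 0:
            raise ModelError("repeatability model requires sigma_pe2 > 0")
        blocks.append(Zp.toarray())
    W = np.hstack(blocks)
    C = W.T @ W
    rhs = W.T @ y
    if vc.sigma_a2 <= 0:
        raise ModelError("sigma_a2 must be positive")
    if vc.sigma_e2 <= 0:
        raise ModelError("sigma_e2 must be positive")
    if scale == "rinv":
        C = C / vc.sigma_e2
        rhs = rhs / vc.sigma_e2
        C[p:p + qa, p:p + qa] += K_inv / vc.sigma_a2
        if Zp is not None:
            qp = Zp.shape[1]
            idx = slice(p + qa, p + qa + qp)
            C[idx, idx] = C[idx, idx] + np.eye(qp) / vc.sigma_pe2
    else:
        C[p:p + qa, p:p + qa] += K_inv * (vc.sigma_e2 / vc.sigma_a2)
        if Zp is not None:
            qp = Zp.shape[1]
            idx = slice(p + qa, p + qa + qp)
            C[idx, idx] = C[idx, idx] + np.eye(qp) * (vc.sigma_e2 / vc.sigma_pe2)
    return C, rhs


def solve_mme(design: DesignBundle, K_inv: RelationshipMatrix, vc: VarianceComponents,
              compute_pev: bool = True, accuracy_mode: str = "sqrt") -> MMESolution:
    """Solve Henderson's mixed-model equations; optionally return PEV/accuracy.

    PEV is exact, from the coefficient-matrix inverse diagonal; reliability
    r² = 1 − PEV/σa², accuracy = √r² (default) or r² itself in literal mode.
    """
    if (K_inv.ids != design.animal_ids).any():
        raise ModelError("K_inv ordering does not match the design's animal ordering")
    Kinv = K_inv.dense()
    C, rhs = _assemble_mme(design, Kinv, vc, scale="rinv")
    p = design.X.shape[1]
    qa = design.Z_animal.shape[1]
    try:
        cf = la.cho_factor(C, lower=True)
    except la.LinAlgError as exc:
        raise EstimabilityError("mixed-model equations are singular") from exc
    sol = la.cho_solve(cf, rhs)

    fixed = pd.Series(sol[:p], index=design.fixed_names)
    ebv = pd.Series(sol[p:p + qa], index=design.animal_ids)
    pe_sol = None
    if design.Z_pe is not None:
        pe_sol = pd.Series(sol[p + qa:], index=design.pe_ids)

    pev = rel = acc = None
    if compute_pev:
        Cinv = la.cho_solve(cf, np.eye(C.shape[0]))
        pev_vals = np.diag(Cinv)[p:p + qa].copy()
        pev = pd.Series(pev_vals, index=design.animal_ids)
        rel, acc = compute_accuracy(pev_vals, vc, mode=accuracy_mode)
        rel = pd.Series(rel, index=design.animal_ids)
        acc = pd.Series(acc, index=design.animal_ids)
    return MMESolution(fixed, ebv, pe_sol, pev, rel, acc, vc)


def compute_accuracy(pev: np.ndarray, vc: VarianceComponents, mode: str = "sqrt"
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Reliability r² = 1 − PEV/σa² and accuracy.

    ``mode='sqrt'`` (default) returns accuracy = √r²; ``mode='literal'``
    returns r² itself, matching a reading of the printed accuracy formula
    that does not take the square root.  Values outside [0, 1] are clipped
    with a warning.
    """
    if vc.sigma_a2 <= 0:
        raise ModelError("accuracy undefined for sigma_a2 = 0")
    if mode not in ("sqrt", "literal"):
        raise ModelError(f"unknown accuracy mode {mode!r}")
    rel = 1.0 - np.asarray(pev, dtype=float) / vc.sigma_a2
    if (rel < -1e-9).any() or (rel > 1 + 1e-9).any():
        logger.warning("reliability outside [0,1] encountered; clipping")
    rel = np.clip(rel, 0.0, 1.0)
    acc = np.sqrt(rel) if mode == "sqrt" else rel
    return rel, acc


# --------------------------------------------------------------------------
# REML


def _reml_workspace(design: DesignBundle) -> dict:
    """Cross-products cached once per REML run (they do not depend on θ)."""
    blocks = [design.X, design.Z_animal.toarray()]
    if design.Z_pe is not None:
        blocks.append(design.Z_pe.toarray())
    W = np.hstack(blocks)
    return {
        "W": W,
        "WtW": W.T @ W,
        "Wty": W.T @ design.y,
        "y": design.y,
        "p": design.X.shape[1],
        "qa": design.Z_animal.shape[1],
        "qp": design.Z_pe.shape[1] if design.Z_pe is not None else 0,
        "n": len(design.y),
    }


def _reml_quantities(work: dict, Kinv: np.ndarray, theta: dict) -> dict:
    """One evaluation of the R⁻¹-scaled MME with everything REML needs."""
    se = theta["sigma_e2"]
    sa = theta["sigma_a2"]
    p, qa, qp, n = work["p"], work["qa"], work["qp"], work["n"]
    C = work["WtW"] / se
    rhs = work["Wty"] / se
    C[p:p + qa, p:p + qa] += Kinv / sa
    if qp:
        idx = slice(p + qa, p + qa + qp)
        C[idx, idx] = C[idx, idx] + np.eye(qp) / theta["sigma_pe2"]
    cf = la.cho_factor(C, lower=True)
    sol = la.cho_solve(cf, rhs)
    Cinv = la.cho_solve(cf, np.eye(C.shape[0]))
    y = work["y"]
    e_hat = y - work["W"] @ sol
    yPy = float(y @ e_hat) / se
    logdetC = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    # -2 restricted loglik up to a constant (log|K| and n·log 2π dropped)
    m2ll = logdetC + n * np.log(se) + qa * np.log(sa) + yPy
    if qp:
        m2ll += qp * np.log(theta["sigma_pe2"])
    a_hat = sol[p:p + qa]
    Waa = Cinv[p:p + qa, p:p + qa]
    out = dict(
        sol=sol, e_hat=e_hat, a_hat=a_hat, loglik=-0.5 * m2ll, yPy=yPy,
        tr_KinvWaa=float(np.sum(Kinv * Waa)),  # tr(K⁻¹ Waa), both symmetric
        aKa=float(a_hat @ (Kinv @ a_hat)),
        C=C, cf=cf, p=p, qa=qa, qp=qp, n=n,
    )
    if qp:
        p_hat = sol[p + qa:]
        out["p_hat"] = p_hat
        out["tr_Wpp"] = float(np.trace(Cinv[p + qa:, p + qa:]))
        out["pp"] = float(p_hat @ p_hat)
    return out


def _reml_scores(q: dict, theta: dict) -> np.ndarray:
    """Exact first derivatives of the restricted loglik w.r.t. (σa² [, σpe²], σe²)."""
    sa, se = theta["sigma_a2"], theta["sigma_e2"]
    qa, qp, n, p = q["qa"], q["qp"], q["n"], q["p"]
    s_a = -0.5 * ((qa * sa - q["tr_KinvWaa"]) / sa**2 - q["aKa"] / sa**2)
    scores = [s_a]
    tr_P = n - p - qa + q["tr_KinvWaa"] / sa
    if qp:
        sp_ = theta["sigma_pe2"]
        s_pe = -0.5 * ((qp * sp_ - q["tr_Wpp"]) / sp_**2 - q["pp"] / sp_**2)
        scores.append(s_pe)
        tr_P += -qp + q["tr_Wpp"] / sp_
    tr_P /= se
    ee = float(q["e_hat"] @ q["e_hat"])
    s_e = -0.5 * (tr_P - ee / se**2)
    scores.append(s_e)
    return np.array(scores)


def _reml_ai_matrix(work: dict, q: dict, theta: dict) -> np.ndarray:
    """Average-information matrix via extra MME solves (f′P f for each component)."""
    p, qa, qp = q["p"], q["qa"], q["qp"]
    se = theta["sigma_e2"]
    W = work["W"]
    fs = [W[:, p:p + qa] @ q["a_hat"] / theta["sigma_a2"]]
    if qp:
        fs.append(W[:, p + qa:] @ q["p_hat"] / theta["sigma_pe2"])
    fs.append(q["e_hat"] / se)
    F = np.column_stack(fs)
    WtF = W.T @ F / se
    PF = (F - W @ la.cho_solve(q["cf"], WtF)) / se
    return 0.5 * (F.T @ PF)


def _em_step(q: dict, theta: dict) -> dict:
    """EM-REML update; guarantees a non-decreasing restricted likelihood."""
    qa, qp, n, p = q["qa"], q["qp"], q["n"], q["p"]
    new = dict(theta)
    new["sigma_a2"] = (q["aKa"] + q["tr_KinvWaa"]) / qa
    if qp:
        new["sigma_pe2"] = (q["pp"] + q["tr_Wpp"]) / qp
    y_ehat = q["yPy"] * theta["sigma_e2"]
    new["sigma_e2"] = y_ehat / (n - p)
    return new


def estimate_reml(design: DesignBundle, K_inv: RelationshipMatrix,
                  init: VarianceComponents | None = None,
                  max_iter: int = 500, tol: float = 1e-8) -> VarianceComponents:
    """AI-REML with EM fallback for (σa², [σpe²,] σe²).

    AI steps are attempted first; a step that leaves the parameter space or
    decreases the restricted likelihood falls back to an EM step.  Collapsing
    components are pinned at a small positive bound.  Non-convergence is
    flagged on the result (with the likelihood trajectory), not raised.
    """
    if (K_inv.ids != design.animal_ids).any():
        raise ModelError("K_inv ordering does not match the design's animal ordering")
    Kinv = K_inv.dense()
    has_pe = design.Z_pe is not None
    vy = float(np.var(design.y))
    floor = max(vy, 1e-12) * 1e-6
    if init is None:
        init = VarianceComponents(
            sigma_a2=0.25 * vy, sigma_e2=0.6 * vy, sigma_pe2=0.15 * vy if has_pe else 0.0
        )
    theta = {"sigma_a2": max(init.sigma_a2, floor), "sigma_e2": max(init.sigma_e2, floor)}
    keys = ["sigma_a2", "sigma_e2"]
    if has_pe:
        theta["sigma_pe2"] = max(init.sigma_pe2, floor)
        keys = ["sigma_a2", "sigma_pe2", "sigma_e2"]

    work = _reml_workspace(design)
    q = _reml_quantities(work, Kinv, theta)
    trajectory = [q["loglik"]]
    converged = False
    AI = None
    for _ in range(max_iter):
        new_theta = None
        try:
            # AI step on the log-variance scale: always positive, well scaled
            # when a component is small; backtrack if the likelihood drops.
            AI = _reml_ai_matrix(work, q, theta)
            g = _reml_scores(q, theta)
            tvec = np.array([theta[k] for k in keys])
            AI_log = AI * np.outer(tvec, tvec)
            step = np.clip(np.linalg.solve(AI_log, g * tvec), -4.0, 4.0)
            gamma = 1.0
            for _halving in range(6):
                cand = {k: max(theta[k] * float(np.exp(gamma * step[i])), floor)
                        for i, k in enumerate(keys)}
                q_cand = _reml_quantities(work, Kinv, cand)
                if q_cand["loglik"] >= trajectory[-1] - 1e-10:
                    new_theta, q_new = cand, q_cand
                    break
                gamma *= 0.5
        except (np.linalg.LinAlgError, la.LinAlgError):
            pass
        if new_theta is None:  # EM fallback
            cand = _em_step(q, theta)
            cand = {k: max(v, floor) for k, v in cand.items()}
            q_new = _reml_quantities(work, Kinv, cand)
            new_theta = cand
        rel_change = max(abs(new_theta[k] - theta[k]) / max(theta[k], floor) for k in keys)
        theta, q = new_theta, q_new
        trajectory.append(q["loglik"])
        if rel_change < tol:
            converged = True
            break
    if not converged:
        logger.warning("REML did not converge in %d iterations", max_iter)

    se = {}
    try:
        AI = _reml_ai_matrix(work, q, theta)
        cov = np.linalg.inv(AI)
        se = {k: float(np.sqrt(max(cov[i, i], 0.0))) for i, k in enumerate(keys)}
    except np.linalg.LinAlgError:
        se = {k: float("nan") for k in keys}
    return VarianceComponents(
        sigma_a2=theta["sigma_a2"],
        sigma_e2=theta["sigma_e2"],
        sigma_pe2=theta.get("sigma_pe2", 0.0),
        standard_errors=se,
        converged=converged,
        loglik_trajectory=trajectory,
    )
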