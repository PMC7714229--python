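"""Single-kernel GBLUP: REML variance components, Henderson's equations, GEBVs.

Model
-----
For a training population of n individuals with phenotype vector y,

    y = mu * 1_n + g + e,
    g ~ MVN(0, sigma_g^2 K),   e ~ MVN(0, sigma_e^2 I_n),

with genomic relationship matrix K = M M^T / p built from the {-1, 0, 1}
marker score matrix M (p SNPs, no centering). Writing lambda =
sigma_e^2 / sigma_g^2, the fixed intercept and the genotypic values solve
Henderson's mixed-model equations

    [ n      1_n^T        ] [ mu_hat ]   [ 1_n^T y ]
    [ 1_n    I_n + lambda K^-1 ] [ g_hat  ] = [ y       ]

whose random-effect part is equivalent to the shrinkage form
g_hat = K (K + lambda I)^-1 (y - mu_hat 1).

Variance components are estimated by restricted maximum likelihood,
profiled down to a one-dimensional search over log(lambda) after a single
spectral decomposition of K.

A breeding population with marker matrix M_bp is scored through

    g_hat_bp = K_bp K^-1 g_hat,   K_bp = M_bp M_train^T / p,

and GEBV = mu_hat + g_hat_bp.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .geno_io import MarkerMatrix, PhenotypeTable

__all__ = [
    "grm",
    "reml_fit",
    "solve_henderson",
    "predict_gebv",
    "gblup_equals_rrblup_check",
    "GBLUP",
    "GBLUPResults",
    "GebvVector",
]

_LAMBDA_BRACKET = (1e-6, 1e6)


def grm(M: np.ndarray, p: int | None = None) -> np.ndarray:
    """Genomic relationship matrix K = M M^T / p.

    ``M`` must be complete with entries in {-1, 0, 1}; ``p`` defaults to the
    number of SNP columns. No marker centering is applied.
    """
    M = np.asarray(M, dtype=float)
    if p is None:
        p = M.shape[1]
    if p == 0:
        raise ValueError("p must be positive")
    if np.isnan(M).any():
        raise ValueError("marker matrix contains missing values; impute first")
    return M @ M.T / p


@dataclass
class GebvVector:
    """Genomic estimated breeding values for a set of individuals."""

    ids: list[str]
    values: np.ndarray
    trait: str = "trait"
    direction: str = "maximize"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.ids) != len(self.values):
            raise ValueError("ids and values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite GEBV")
        if self.direction not in ("maximize", "minimize"):
            raise ValueError("direction must be maximize|minimize")

    def __len__(self) -> int:
        return len(self.values)

    def directed_order(self) -> np.ndarray:
        """Indices from best to worst in the configured direction.

        Ties are broken by position, i.e. input (id) order, via stable sort.
        """
        key = -self.values if self.direction == "maximize" else self.values
        return np.argsort(key, kind="stable")

    def top(self, k: int) -> list[str]:
        return [self.ids[i] for i in self.directed_order()[:k]]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"id": self.ids, "trait": self.trait, "gebv": self.values})


class _ProfiledREML:
    """Restricted likelihood of the intercept-only GBLUP, profiled over lambda.

    With K = U diag(s) U^T, rotate y and the intercept column once; for a
    candidate lambda the weights are w = s + lambda, the GLS intercept and
    residual sum of squares follow in O(n), and sigma_g^2 is profiled out as
    RSS / (n - 1). Up to an additive constant the restricted log-likelihood
    is

        -1/2 [ (n-1) log sigma_g^2 + sum log w + log sum(x_i^2 / w_i) ].
    """

    def __init__(self, y: np.ndarray, K: np.ndarray):
        y = np.asarray(y, dtype=float)
        n = len(y)
        if n < 3:
            raise ValueError("need at least 3 individuals for REML")
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite phenotype")
        s, U = np.linalg.eigh((K + K.T) / 2.0)
        self.s = np.maximum(s, 0.0)  # clip tiny negative eigenvalues of PSD K
        self.yt = U.T @ y
        self.xt = U.T @ np.ones(n)
        self.n = n

    def mu_sigma2(self, lam: float) -> tuple[float, float]:
        w = self.s + lam
        sxx = np.sum(self.xt**2 / w)
        mu = np.sum(self.xt * self.yt / w) / sxx
        rss = np.sum((self.yt - mu * self.xt) ** 2 / w)
        return mu, rss / (self.n - 1)

    def loglik(self, lam: float) -> float:
        w = self.s + lam
        sxx = np.sum(self.xt**2 / w)
        mu = np.sum(self.xt * self.yt / w) / sxx
        rss = np.sum((self.yt - mu * self.xt) ** 2 / w)
        sigma2 = rss / (self.n - 1)
        if sigma2 <= 0:
            return -np.inf
        return -0.5 * ((self.n - 1) * np.log(sigma2) + np.sum(np.log(w)) + np.log(sxx))

    def optimize(self, bracket=_LAMBDA_BRACKET, tol: float = 1e-8):
        lo, hi = np.log(bracket[0]), np.log(bracket[1])
        # coarse scan to localize the optimum, then Brent within the winning cell
        grid = np.linspace(lo, hi, 61)
        vals = np.array([self.loglik(np.exp(t)) for t in grid])
        i = int(np.argmax(vals))
        a, b = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
        res = minimize_scalar(
            lambda t: -self.loglik(np.exp(t)),
            bounds=(a, b), method="bounded", options={"xatol": tol},
        )
        cands = [(np.exp(res.x), self.loglik(np.exp(res.x)), False)]
        cands.append((bracket[0], self.loglik(bracket[0]), True))
        cands.append((bracket[1], self.loglik(bracket[1]), True))
        lam, ll, at_boundary = max(cands, key=lambda c: c[1])
        return lam, ll, at_boundary


def reml_fit(
    y: np.ndarray, K: np.ndarray, bracket=_LAMBDA_BRACKET, tol: float = 1e-8
) -> tuple[float, float, float]:
    """REML estimates (sigma_g^2, sigma_e^2, lambda) for the GBLUP model.

    Maximizes the restricted likelihood over the variance ratio by a
    bracketed one-dimensional search on log(lambda) after one spectral
    decomposition of K; both bracket endpoints are evaluated as boundary
    candidates.
    """
    prof = _ProfiledREML(y, np.asarray(K, dtype=float))
    lam, _, _ = prof.optimize(bracket, tol)
    _, sigma2_g = prof.mu_sigma2(lam)
    return sigma2_g, lam * sigma2_g, lam


def solve_henderson(
    y: np.ndarray, K: np.ndarray, lam: float
) -> tuple[float, np.ndarray]:
    """Solve the mixed-model equations for (mu_hat, g_hat) at a fixed lambda.

    Uses the shrinkage form: mu_hat is the GLS intercept under
    V proportional to K + lambda I, and g_hat = K (K + lambda I)^-1
    (y - mu_hat 1), which is the unique solution of Henderson's bordered
    system when K is invertible and its natural pseudoinverse extension
    otherwise.
    """
    y = np.asarray(y, dtype=float)
    K = np.asarray(K, dtype=float)
    if lam <= 0:
        raise ValueError("lambda must be positive")
    n = len(y)
    V = K + lam * np.eye(n)
    try:
        Vi_y = np.linalg.solve(V, y)
        Vi_1 = np.linalg.solve(V, np.ones(n))
    except np.linalg.LinAlgError as exc:  # V is PD for lam > 0 and PSD K
        raise np.linalg.LinAlgError("singular mixed-model system") from exc
    mu = float(np.ones(n) @ Vi_y / (np.ones(n) @ Vi_1))
    g = K @ np.linalg.solve(V, y - mu)
    return mu, g


def _as_matrix(M) -> np.ndarray:
    if isinstance(M, MarkerMatrix):
        return M.scores
    return np.asarray(M, dtype=float)


@dataclass
class GBLUPResults:
    """Fitted GBLUP model: estimates, variance components, and prediction."""

    mu_hat: float
    g_hat: np.ndarray
    sigma2_g: float
    sigma2_e: float
    lam: float
    K: np.ndarray
    M_train: np.ndarray
    snp_ids: list[str] | None
    accession_ids: list[str]
    trait: str = "trait"
    direction: str = "maximize"
    loglik: float = np.nan
    boundary: bool = False
    _K_inv: np.ndarray | None = field(default=None, repr=False)
    _alpha: np.ndarray | None = field(default=None, repr=False)

    @property
    def h2(self) -> float:
        """Genomic heritability sigma_g^2 / (sigma_g^2 + sigma_e^2)."""
        tot = self.sigma2_g + self.sigma2_e
        return float(self.sigma2_g / tot) if tot > 0 else np.nan

    @property
    def K_inv(self) -> np.ndarray:
        """Moore-Penrose pseudoinverse of K (relative tolerance 1e-10)."""
        if self._K_inv is None:
            self._K_inv = np.linalg.pinv(self.K, rcond=1e-10, hermitian=True)
        return self._K_inv

    @property
    def alpha(self) -> np.ndarray:
        """K^-1 g_hat, in the numerically stable form (K + lambda I)^-1 (y - mu 1).

        For K_bp rows lying in the row space of the training markers —
        always true for K_bp = M_bp M_train^T / p — K_bp @ alpha equals
        K_bp K^-1 g_hat exactly, without forming a pseudoinverse.
        """
        if self._alpha is None:
            resid = self.__dict__.get("_resid_cache")
            if resid is not None:
                V = self.K + self.lam * np.eye(len(self.g_hat))
                self._alpha = np.linalg.solve(V, resid)
            else:  # reloaded fit: g_hat lies in range(K), so pinv is exact
                self._alpha = self.K_inv @ self.g_hat
        return self._alpha

    def gebv_train(self) -> GebvVector:
        """GEBVs of the training individuals: mu_hat + g_hat."""
        return GebvVector(
            ids=list(self.accession_ids), values=self.mu_hat + self.g_hat,
            trait=self.trait, direction=self.direction,
        )

    def predict(self, M_bp, ids: Sequence[str] | None = None) -> GebvVector:
        """GEBVs for a breeding population genotyped on the training SNP set.

        ``M_bp`` is a MarkerMatrix (SNP ids checked against training order)
        or a bare score matrix assumed aligned.
        """
        if isinstance(M_bp, MarkerMatrix):
            if self.snp_ids is not None and list(M_bp.snp_ids) != list(self.snp_ids):
                for a, b in zip(M_bp.snp_ids, self.snp_ids):
                    if a != b:
                        raise ValueError(
                            f"SNP misalignment: breeding population has {a!r} "
                            f"where training has {b!r}"
                        )
                raise ValueError("SNP count mismatch with training markers")
            if ids is None:
                ids = M_bp.accession_ids
        X = _as_matrix(M_bp)
        if X.shape[1] != self.M_train.shape[1]:
            raise ValueError("breeding population SNP count mismatch")
        p = self.M_train.shape[1]
        K_bp = X @ self.M_train.T / p
        vals = self.mu_hat + K_bp @ self.alpha
        if ids is None:
            ids = [f"bp_{i}" for i in range(len(vals))]
        return GebvVector(list(ids), vals, trait=self.trait, direction=self.direction)

    def summary(self) -> str:
        lines = [
            "GBLUP results",
            "=" * 46,
            f"trait:            {self.trait} ({self.direction})",
            f"n individuals:    {len(self.g_hat)}",
            f"p SNPs:           {self.M_train.shape[1]}",
            f"mu_hat:           {self.mu_hat:.6g}",
            f"sigma2_g:         {self.sigma2_g:.6g}",
            f"sigma2_e:         {self.sigma2_e:.6g}",
            f"lambda (e/g):     {self.lam:.6g}" + ("  [boundary]" if self.boundary else ""),
            f"genomic h2:       {self.h2:.4f}",
            f"restricted llf:   {self.loglik:.6g}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def to_json(self, path) -> None:
        """Persist the fit as a structured-text artifact with a version tag."""
        obj = {
            "format": "gpsel.gblup-fit",
            "version": 1,
            "trait": self.trait,
            "direction": self.direction,
            "mu_hat": self.mu_hat,
            "sigma2_g": self.sigma2_g,
            "sigma2_e": self.sigma2_e,
            "lambda": self.lam,
            "loglik": None if np.isnan(self.loglik) else self.loglik,
            "boundary": self.boundary,
            "accession_ids": list(self.accession_ids),
            "snp_ids": None if self.snp_ids is None else list(self.snp_ids),
            "g_hat": self.g_hat.tolist(),
            "M_train": self.M_train.astype(int).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "GBLUPResults":
        with open(path) as fh:
            obj = json.load(fh)
        if obj.get("format") != "gpsel.gblup-fit":
            raise ValueError("not a gpsel GBLUP fit artifact")
        M = np.asarray(obj["M_train"], dtype=float)
        res = cls(
            mu_hat=obj["mu_hat"], g_hat=np.asarray(obj["g_hat"]),
            sigma2_g=obj["sigma2_g"], sigma2_e=obj["sigma2_e"], lam=obj["lambda"],
            K=grm(M), M_train=M, snp_ids=obj["snp_ids"],
            accession_ids=obj["accession_ids"], trait=obj["trait"],
            direction=obj["direction"],
            loglik=np.nan if obj["loglik"] is None else obj["loglik"],
            boundary=obj["boundary"],
        )
        return res

    def __post_init__(self) -> None:
        self.g_hat = np.asarray(self.g_hat, dtype=float)


class GBLUP:
    """Intercept-only GBLUP model for one quantitative trait.

    Parameters
    ----------
    endog : array-like
        Phenotype vector of the training population.
    markers : MarkerMatrix or ndarray
        Complete {-1, 0, 1} score matrix aligned to ``endog``; K = M M^T / p
        is built from it.
    ids, trait, direction :
        Bookkeeping carried through to results and GEBV vectors.

    Examples
    --------
    >>> model = GBLUP(y, markers=M, trait="yield", direction="maximize")
    >>> res = model.fit()
    >>> print(res.summary())
    >>> gebvs = res.predict(progeny_scores)
    """

    def __init__(
        self,
        endog,
        markers,
        ids: Sequence[str] | None = None,
        trait: str = "trait",
        direction: str = "maximize",
    ):
        self.y = np.asarray(endog, dtype=float)
        if isinstance(markers, MarkerMatrix):
            if markers.n_accessions != len(self.y):
                raise ValueError("phenotype / marker matrix row mismatch")
            self.M = markers.scores
            self.snp_ids: list[str] | None = list(markers.snp_ids)
            ids = ids or list(markers.accession_ids)
        else:
            self.M = np.asarray(markers, dtype=float)
            self.snp_ids = None
        if self.M.shape[0] != len(self.y):
            raise ValueError("phenotype / marker matrix row mismatch")
        self.ids = list(ids) if ids is not None else [str(i) for i in range(len(self.y))]
        self.trait = trait
        self.direction = direction
        self.K = grm(self.M)

    @classmethod
    def from_dataframe(
        cls, pheno: PhenotypeTable, markers: MarkerMatrix, trait: str
    ) -> "GBLUP":
        """Build from a phenotype table and marker matrix, intersecting ids.

        Only accessions with a non-missing phenotype for ``trait`` enter the
        training set; marker rows are aligned to them by id.
        """
        pheno.check_against(markers)
        y = pheno.trait(trait).dropna()
        sub = markers.take_accessions(list(y.index))
        return cls(
            y.to_numpy(), sub, ids=list(y.index), trait=trait,
            direction=pheno.direction(trait),
        )

    def fit(
        self,
        lam: float | None = None,
        bracket=_LAMBDA_BRACKET,
        tol: float = 1e-8,
    ) -> GBLUPResults:
        """Estimate variance components by REML and solve Henderson's equations.

        Pass ``lam`` to skip REML and fit at a fixed variance ratio.
        """
        if lam is None:
            prof = _ProfiledREML(self.y, self.K)
            lam_hat, ll, boundary = prof.optimize(bracket, tol)
            _, sigma2_g = prof.mu_sigma2(lam_hat)
        else:
            prof = _ProfiledREML(self.y, self.K)
            lam_hat, boundary = float(lam), False
            ll = prof.loglik(lam_hat)
            _, sigma2_g = prof.mu_sigma2(lam_hat)
        mu, g = solve_henderson(self.y, self.K, lam_hat)
        res = GBLUPResults(
            mu_hat=mu, g_hat=g, sigma2_g=sigma2_g, sigma2_e=lam_hat * sigma2_g,
            lam=lam_hat, K=self.K, M_train=self.M, snp_ids=self.snp_ids,
            accession_ids=self.ids, trait=self.trait, direction=self.direction,
            loglik=ll, boundary=boundary,
        )
        res.__dict__["_resid_cache"] = self.y - mu
        return res


def predict_gebv(fit: GBLUPResults, M_bp, ids=None) -> GebvVector:
    """Functional alias for :meth:`GBLUPResults.predict`."""
    return fit.predict(M_bp, ids=ids)


def gblup_equals_rrblup_check(M, y, lam: float | None = None) -> float:
    """Max |GEBV_gblup - GEBV_rrblup| over training individuals.

    Fits ridge-regression BLUP on marker effects with the matched penalty
    (lambda_marker = p * lambda for K = M M^T / p) and GBLUP at the same
    lambda and intercept, then compares training GEBVs. The two
    formulations are algebraically identical, so the discrepancy measures
    numerical error only.
    """
    M = _as_matrix(M)
    y = np.asarray(y, dtype=float)
    n, p = M.shape
    K = grm(M)
    if lam is None:
        _, _, lam = reml_fit(y, K)
    mu, g = solve_henderson(y, K, lam)
    gebv_gblup = mu + g
    # marker-effect ridge at the matched penalty
    A = M.T @ M + p * lam * np.eye(p)
    beta = np.linalg.solve(A, M.T @ (y - mu))
    gebv_rr = mu + M @ beta
    return float(np.max(np.abs(gebv_gblup - gebv_rr)))
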