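"""Pedigree and genomic relationship matrices for single-step evaluation.

Builds the numerator relationship matrix **A** (tabular method, with
inbreeding), its sparse inverse (Henderson's rules with Mendelian
sampling variances), the VanRaden genomic matrix **G0**, the blended and
tuned **G**, and the single-step inverse

    H^-1 = A^-1 + [0 0; 0 G^-1 - A22^-1]

over a pedigree with a genotyped subset.  ``A22`` is the pedigree
relationship among genotyped animals.  Also provides the marker quality
control applied before building G: individual call rate, SNP missingness,
minor allele frequency and a Hardy-Weinberg chi-square filter, autosomes
only.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.stats import chi2


# ---------------------------------------------------------------------------
# pedigree container
# ---------------------------------------------------------------------------

class PedigreeError(ValueError):
    pass


class Pedigree:
    """A validated pedigree in parents-first order.

    Parameters
    ----------
    ids : array of animal identifiers (any hashable type)
    sire_idx, dam_idx : int arrays
        Positional parent indices into ``ids``; ``-1`` marks an unknown
        parent.  Parents must precede offspring.
    meta : optional DataFrame aligned with ``ids`` (sex, generation, ...).
    """

    def __init__(self, ids, sire_idx, dam_idx, meta: pd.DataFrame | None = None):
        self.ids = np.asarray(ids)
        self.sire_idx = np.asarray(sire_idx, dtype=np.int64)
        self.dam_idx = np.asarray(dam_idx, dtype=np.int64)
        self.meta = meta
        n = len(self.ids)
        if len(self.sire_idx) != n or len(self.dam_idx) != n:
            raise PedigreeError("ids and parent arrays must have equal length")
        pos = np.arange(n)
        for par in (self.sire_idx, self.dam_idx):
            if par.max(initial=-1) >= n:
                raise PedigreeError("parent index out of range")
            if np.any(par >= pos):
                raise PedigreeError("pedigree loop: a parent does not precede its offspring")
        self._pos = {a: i for i, a in enumerate(self.ids)}

    def __len__(self):
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids) -> np.ndarray:
        """Positional indices of the given animal identifiers."""
        return np.asarray([self._pos[a] for a in np.asarray(ids)], dtype=np.int64)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, unknown=0) -> "Pedigree":
        """Build from an id/sire/dam table; ``unknown`` codes a missing parent.

        Rows are topologically sorted so parents precede offspring; a
        cyclic pedigree raises :class:`PedigreeError`.
        """
        ids = df["id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise PedigreeError("duplicate animal ids")
        pos = {a: i for i, a in enumerate(ids)}
        sire = df["sire"].to_numpy()
        dam = df["dam"].to_numpy()

        # Kahn topological sort on parent -> offspring edges
        n = len(ids)
        children = [[] for _ in range(n)]
        indeg = np.zeros(n, dtype=int)
        for i in range(n):
            for p in (sire[i], dam[i]):
                if p != unknown:
                    if p not in pos:
                        raise PedigreeError(f"parent {p!r} not in pedigree")
                    children[pos[p]].append(i)
                    indeg[i] += 1
        order = [i for i in range(n) if indeg[i] == 0]
        head = 0
        while head < len(order):
            for c in children[order[head]]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    order.append(c)
            head += 1
        if len(order) != n:
            raise PedigreeError("pedigree loop detected")
        order = np.asarray(order)
        new_pos = np.empty(n, dtype=np.int64)
        new_pos[order] = np.arange(n)
        ids2 = ids[order]
        remap = {a: i for i, a in enumerate(ids2)}

        def par_idx(arr):
            return np.asarray(
                [remap[p] if p != unknown else -1 for p in arr[order]], dtype=np.int64
            )

        meta = df.drop(columns=["id", "sire", "dam"]).iloc[order].reset_index(drop=True)
        if meta.shape[1] == 0:
            meta = None
        return cls(ids2, par_idx(sire), par_idx(dam), meta=meta)

    def to_frame(self, unknown=0) -> pd.DataFrame:
        sire = np.where(self.sire_idx >= 0, self.ids[np.maximum(self.sire_idx, 0)], unknown)
        dam = np.where(self.dam_idx >= 0, self.ids[np.maximum(self.dam_idx, 0)], unknown)
        return pd.DataFrame({"id": self.ids, "sire": sire, "dam": dam})


# ---------------------------------------------------------------------------
# pedigree relationships
# ---------------------------------------------------------------------------

def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen-Luo ancestor-tracing method."""
    n = ped.n
    s, d = ped.sire_idx, ped.dam_idx
    F = np.zeros(n)
    # Mendelian sampling variances, filled in sequentially
    D = np.zeros(n)
    for i in range(n):
        if s[i] < 0 and d[i] < 0:
            D[i] = 1.0
        elif s[i] < 0:
            D[i] = 0.75 - 0.25 * F[d[i]]
        elif d[i] < 0:
            D[i] = 0.75 - 0.25 * F[s[i]]
        else:
            D[i] = 0.5 - 0.25 * (F[s[i]] + F[d[i]])
        if s[i] < 0 or d[i] < 0:
            F[i] = 0.0
            continue
        # accumulate L_ij over ancestors j of i, processing indices descending
        coef = {i: 1.0}
        heap = [-i]
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            if j not in coef:
                continue
            v = coef.pop(j)
            aii += v * v * D[j]
            for p in (s[j], d[j]):
                if p >= 0:
                    if p in coef:
                        coef[p] += 0.5 * v
                    else:
                        coef[p] = 0.5 * v
                        heapq.heappush(heap, -p)
        F[i] = aii - 1.0
    return F


def mendelian_variances(ped: Pedigree, F: np.ndarray | None = None) -> np.ndarray:
    """Mendelian sampling variances d_i used by Henderson's A-inverse rules."""
    if F is None:
        F = inbreeding(ped)
    s, d = ped.sire_idx, ped.dam_idx
    D = np.empty(ped.n)
    both = (s >= 0) & (d >= 0)
    none = (s < 0) & (d < 0)
    one = ~both & ~none
    D[none] = 1.0
    Fs = np.where(s >= 0, F[np.maximum(s, 0)], 0.0)
    Fd = np.where(d >= 0, F[np.maximum(d, 0)], 0.0)
    D[both] = 0.5 - 0.25 * (Fs[both] + Fd[both])
    D[one] = 0.75 - 0.25 * (Fs[one] + Fd[one])
    return D


def make_A(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular (recursive) method.

    Intended for small to moderate pedigrees (oracles, A22 blocks); memory
    is O(n^2).
    """
    n = ped.n
    s, d = ped.sire_idx, ped.dam_idx
    A = np.zeros((n, n))
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            A[i, i] = 1.0 + 0.5 * A[si, di]
        else:
            A[i, i] = 1.0
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * A[si, :i]
        if di >= 0:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
    return A


def make_A_inverse(ped: Pedigree, F: np.ndarray | None = None):
    """Sparse A^-1 by Henderson's rules with inbreeding.

    Returns ``(A_inv, logdet_A)`` where ``logdet_A = sum(log d_i)`` from
    the T D T' decomposition of A.
    """
    D = mendelian_variances(ped, F)
    s, d = ped.sire_idx, ped.dam_idx
    n = ped.n
    rows, cols, vals = [], [], []
    inv_d = 1.0 / D
    for i in range(n):
        b = inv_d[i]
        rows.append(i); cols.append(i); vals.append(b)
        for p in (s[i], d[i]):
            if p >= 0:
                rows += [i, p]; cols += [p, i]; vals += [-0.5 * b, -0.5 * b]
        for p in (s[i], d[i]):
            if p >= 0:
                rows.append(p); cols.append(p); vals.append(0.25 * b)
        if s[i] >= 0 and d[i] >= 0:
            rows += [s[i], d[i]]; cols += [d[i], s[i]]; vals += [0.25 * b, 0.25 * b]
    A_inv = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    return A_inv, float(np.sum(np.log(D)))


def A_submatrix(ped: Pedigree, idx: np.ndarray) -> np.ndarray:
    """Columns/rows of A for the given animals without forming all of A.

    Uses the decomposition A = (I-P)^-1 D (I-P)^-T (Colleau's indirect
    method): each requested column is two sparse triangular solves.
    """
    idx = np.asarray(idx, dtype=np.int64)
    n = ped.n
    D = mendelian_variances(ped)
    rows, cols, vals = [], [], []
    for i in range(n):
        for p in (ped.sire_idx[i], ped.dam_idx[i]):
            if p >= 0:
                rows.append(i); cols.append(p); vals.append(0.5)
    P = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    ImP = sp.eye(n, format="csc") - P
    lu = spla.splu(ImP, permc_spec="NATURAL")
    E = np.zeros((n, len(idx)))
    E[idx, np.arange(len(idx))] = 1.0
    T = lu.solve(E, trans="T")      # (I-P)^-T E
    T *= D[:, None]
    cols_A = lu.solve(T)            # (I-P)^-1 D (I-P)^-T E
    return cols_A[idx, :]


# ---------------------------------------------------------------------------
# genomic relationships
# ---------------------------------------------------------------------------

def allele_frequencies(genotypes: np.ndarray) -> np.ndarray:
    """Observed allele frequencies from a 0/1/2 matrix (missing < 0 or NaN)."""
    g = np.asarray(genotypes, dtype=float)
    g = np.where(g < 0, np.nan, g)
    return np.nanmean(g, axis=0) / 2.0


def vanraden_G(genotypes: np.ndarray, freqs: np.ndarray | None = None):
    """VanRaden method-1 genomic relationship matrix.

    G0 = M M' / (2 sum p_j (1 - p_j)), with M the genotype matrix centred
    by twice the allele frequency; missing genotypes are imputed to the
    mean (2 p_j).  Returns ``(G0, freqs, scale)`` where ``scale`` is the
    denominator 2*sum(p*q).
    """
    g = np.asarray(genotypes, dtype=float)
    g = np.where(g < 0, np.nan, g)
    if freqs is None:
        freqs = np.nanmean(g, axis=0) / 2.0
    M = g - 2.0 * freqs
    M = np.where(np.isnan(M), 0.0, M)
    scale = 2.0 * np.sum(freqs * (1.0 - freqs))
    if scale <= 0:
        raise ValueError("all SNPs monomorphic: zero VanRaden denominator")
    G0 = (M @ M.T) / scale
    return G0, freqs, scale


def blend_tune_G(
    G0: np.ndarray, A22: np.ndarray, omega: float = 0.05, tune: bool = True
):
    """Tune G0 to the scale of A22, then blend: G = (1-w) G* + w A22.

    Tuning solves ``alpha + beta * G0`` such that the means of the
    diagonal and of the off-diagonal match those of A22 (the two-moment
    adjustment of the ssGBLUP software lineage).  Returns
    ``(G, (alpha, beta))``.
    """
    G0 = np.asarray(G0, dtype=float)
    A22 = np.asarray(A22, dtype=float)
    if G0.shape != A22.shape:
        raise ValueError("G0 and A22 are not conformable")
    if tune:
        n = G0.shape[0]
        off = ~np.eye(n, dtype=bool)
        md_g, mo_g = G0.diagonal().mean(), G0[off].mean()
        md_a, mo_a = A22.diagonal().mean(), A22[off].mean()
        denom = md_g - mo_g
        if abs(denom) < 1e-12:
            raise ValueError("constant G0: tuning system is singular")
        beta = (md_a - mo_a) / denom
        alpha = md_a - beta * md_g
        G_star = alpha + beta * G0
    else:
        alpha, beta = 0.0, 1.0
        G_star = G0
    G = (1.0 - omega) * G_star + omega * A22
    return G, (alpha, beta)


def h_inverse(
    A_inv: sp.spmatrix,
    A22: np.ndarray,
    G: np.ndarray,
    genotyped_idx: np.ndarray,
    verbatim: bool = False,
):
    """Single-step H^-1 = A^-1 + [0 0; 0 G^-1 - A22^-1].

    ``genotyped_idx`` are positions of genotyped animals in pedigree
    order.  ``verbatim=True`` subtracts A22 itself instead of its inverse
    (the formula as printed in some papers; kept for comparison only).
    Returns a CSC matrix.
    """
    genotyped_idx = np.asarray(genotyped_idx, dtype=np.int64)
    n = A_inv.shape[0]
    if len(genotyped_idx) == 0:
        return A_inv.tocsc().copy()
    G_inv = np.linalg.inv(G)
    block = G_inv - (A22 if verbatim else np.linalg.inv(A22))
    r = np.repeat(genotyped_idx, len(genotyped_idx))
    c = np.tile(genotyped_idx, len(genotyped_idx))
    add = sp.csc_matrix((block.ravel(), (r, c)), shape=(n, n))
    return (A_inv.tocsc() + add).tocsc()


# ---------------------------------------------------------------------------
# kinship wrapper used by the models
# ---------------------------------------------------------------------------

@dataclass
class Kinship:
    """A relationship structure K presented through its inverse.

    The REML machinery needs K^-1 (sparse), log|K| and products K @ v.
    """

    inv: sp.spmatrix
    logdet: float
    ids: np.ndarray
    label: str = "A"

    def __post_init__(self):
        self.inv = sp.csc_matrix(self.inv)
        self._lu = None

    @property
    def n(self) -> int:
        return self.inv.shape[0]

    def dot(self, v: np.ndarray) -> np.ndarray:
        """K @ v computed as a solve against K^-1."""
        if self._lu is None:
            if self.inv.nnz > 0.2 * self.n**2:
                from scipy.linalg import cho_factor, cho_solve

                cf = cho_factor(self.inv.toarray(), lower=True, check_finite=False)
                self._lu = lambda b: cho_solve(cf, b, check_finite=False)
            else:
                lu = spla.splu(self.inv.tocsc(), permc_spec="MMD_AT_PLUS_A")
                self._lu = lu.solve
        return self._lu(np.asarray(v, dtype=float))

    def save(self, path):
        """Persist K^-1 (CSC parts), log|K| and the animal-id index (.npz)."""
        inv = self.inv.tocsc()
        np.savez_compressed(
            path, data=inv.data, indices=inv.indices, indptr=inv.indptr,
            shape=np.asarray(inv.shape), logdet=np.asarray([self.logdet]),
            ids=np.asarray(self.ids), label=np.asarray([self.label]),
        )

    @classmethod
    def load(cls, path) -> "Kinship":
        with np.load(path, allow_pickle=False) as z:
            inv = sp.csc_matrix(
                (z["data"], z["indices"], z["indptr"]), shape=tuple(z["shape"]))
            return cls(inv, float(z["logdet"][0]), z["ids"], label=str(z["label"][0]))

    @classmethod
    def from_pedigree(cls, ped: Pedigree) -> "Kinship":
        A_inv, logdet = make_A_inverse(ped)
        return cls(A_inv, logdet, ped.ids, label="A")

    @classmethod
    def from_grm(cls, G: np.ndarray, ids) -> "Kinship":
        """Purely genomic kinship (all animals genotyped)."""
        sign, logdet = np.linalg.slogdet(G)
        if sign <= 0:
            raise ValueError("G is not positive definite")
        return cls(sp.csc_matrix(np.linalg.inv(G)), logdet, np.asarray(ids), label="G")

    @classmethod
    def single_step(
        cls,
        ped: Pedigree,
        genotyped_ids,
        genotypes: np.ndarray,
        omega: float = 0.05,
        tune: bool = True,
        verbatim: bool = False,
    ) -> "Kinship":
        """Blended pedigree-genomic H from a pedigree and a genotyped subset."""
        gidx = ped.index_of(genotyped_ids)
        A_inv, logdet_A = make_A_inverse(ped)
        A22 = A_submatrix(ped, gidx)
        G0, _, _ = vanraden_G(genotypes)
        G, _ = blend_tune_G(G0, A22, omega=omega, tune=tune)
        H_inv = h_inverse(A_inv, A22, G, gidx, verbatim=verbatim)
        sign_g, logdet_G = np.linalg.slogdet(G)
        sign_a, logdet_A22 = np.linalg.slogdet(A22)
        if sign_g <= 0:
            raise ValueError("blended G is not positive definite")
        logdet_H = logdet_A + logdet_G - logdet_A22
        return cls(H_inv, logdet_H, ped.ids, label="H")


# ---------------------------------------------------------------------------
# genotype quality control
# ---------------------------------------------------------------------------

@dataclass
class QcReport:
    """Counts of SNPs/individuals removed by each quality-control rule."""

    n_snps_in: int = 0
    n_snps_out: int = 0
    n_ind_in: int = 0
    n_ind_out: int = 0
    removed: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_snps_in": self.n_snps_in,
            "n_snps_out": self.n_snps_out,
            "n_ind_in": self.n_ind_in,
            "n_ind_out": self.n_ind_out,
            "removed": dict(self.removed),
        }


_NON_AUTOSOMES = {"X", "Y", "XY", "MT", "M", "0"}


def hwe_pvalues(genotypes: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg chi-square (1 df) p-value per SNP (missing < 0 ignored)."""
    g = np.asarray(genotypes, dtype=float)
    g = np.where(g < 0, np.nan, g)
    n = np.sum(~np.isnan(g), axis=0).astype(float)
    n0 = np.nansum(g == 0, axis=0)
    n1 = np.nansum(g == 1, axis=0)
    n2 = np.nansum(g == 2, axis=0)
    p = (2 * n2 + n1) / (2 * np.maximum(n, 1))
    q = 1 - p
    with np.errstate(divide="ignore", invalid="ignore"):
        e0, e1, e2 = n * q**2, 2 * n * p * q, n * p**2
        stat = (n0 - e0) ** 2 / e0 + (n1 - e1) ** 2 / e1 + (n2 - e2) ** 2 / e2
    stat = np.where(np.isfinite(stat), stat, 0.0)  # monomorphic: no HWE evidence
    return chi2.sf(stat, df=1)


def qc_genotypes(
    genotypes: np.ndarray,
    snp_map: pd.DataFrame,
    ids=None,
    maf_min: float = 0.05,
    max_missing: float = 0.10,
    hwe_p: float = 1e-5,
    min_call_rate: float = 0.90,
):
    """Marker and individual quality control.

    Filters, in order: individual call rate < ``min_call_rate``; SNP
    missing rate > ``max_missing``; minor allele frequency < ``maf_min``
    (monomorphic SNPs fall here); Hardy-Weinberg chi-square p <=
    ``hwe_p``; non-autosomal SNPs.  Missing genotypes are coded negative
    (or NaN).

    Returns ``(genotypes, snp_map, kept_ids, QcReport)``.
    """
    g = np.asarray(genotypes, dtype=float)
    g = np.where(np.isnan(g), -1.0, g)
    n_ind, n_snp = g.shape
    report = QcReport(n_snps_in=n_snp, n_ind_in=n_ind)
    ids = np.arange(n_ind) if ids is None else np.asarray(ids)

    miss = g < 0
    call_rate = 1.0 - miss.mean(axis=1)
    keep_ind = call_rate >= min_call_rate
    report.removed["individual_call_rate"] = int((~keep_ind).sum())
    g = g[keep_ind]
    ids = ids[keep_ind]

    keep = np.ones(n_snp, dtype=bool)
    chrom = snp_map["chrom"].astype(str).str.upper().to_numpy()
    autosomal = ~np.isin(chrom, list(_NON_AUTOSOMES))
    report.removed["non_autosomal"] = int((~autosomal).sum())
    keep &= autosomal

    snp_missing = (g < 0).mean(axis=0)
    bad = keep & (snp_missing > max_missing)
    report.removed["missing_rate"] = int(bad.sum())
    keep &= ~bad

    freq = allele_frequencies(g)
    maf = np.minimum(freq, 1 - freq)
    bad = keep & (maf < maf_min)
    report.removed["maf"] = int(bad.sum())
    keep &= ~bad

    pvals = hwe_pvalues(g)
    bad = keep & (pvals <= hwe_p)
    report.removed["hwe"] = int(bad.sum())
    keep &= ~bad

    report.n_snps_out = int(keep.sum())
    report.n_ind_out = len(ids)
    if report.n_snps_out == 0:
        raise ValueError("no SNPs survive quality control")
    out = np.asarray(genotypes)[np.ix_(keep_ind, keep)]
    return out, snp_map[keep].reset_index(drop=True), ids, report
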