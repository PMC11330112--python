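"""Compact numpy implementation of the sparse-gene BiLSTM network.

The network is small by construction (hidden size 4 per LSTM direction, one
scalar feature per gene), so forward and backward passes are written directly
against numpy with exact hand-derived gradients; correctness is pinned by
finite-difference tests.  Layout:

  encoded SNPs --(masked linear, per-gene)--> gene scalars, grouped by chrom
  per chromosome: BiLSTM over genes in genomic order -> concatenated h_t
  all chromosomes' outputs + standardized covariates --(linear + sigmoid)--> score

The ``no_partial`` variant skips the masked layer and feeds encoded SNPs
directly as the per-chromosome sequences.
"""

from __future__ import annotations

import numpy as np

from .feature_encoding import ConnectivityMap

HIDDEN = 4  # per-direction LSTM hidden units


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _lstm_forward(x: np.ndarray, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray):
    """x: (T, B, d) -> hidden states (T, B, H) plus cache for BPTT."""
    T, B, _ = x.shape
    H = HIDDEN
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    hs = np.empty((T, B, H))
    cache = {
        "x": x,
        "i": np.empty((T, B, H)), "f": np.empty((T, B, H)),
        "g": np.empty((T, B, H)), "o": np.empty((T, B, H)),
        "c_prev": np.empty((T, B, H)), "h_prev": np.empty((T, B, H)),
        "tanh_c": np.empty((T, B, H)),
    }
    for t in range(T):
        cache["h_prev"][t] = h
        cache["c_prev"][t] = c
        z = x[t] @ Wx + h @ Wh + b
        i = sigmoid(z[:, :H])
        f = sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = sigmoid(z[:, 3 * H:])
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        hs[t] = h
        cache["i"][t], cache["f"][t], cache["g"][t], cache["o"][t] = i, f, g, o
        cache["tanh_c"][t] = tc
    return hs, cache


def _lstm_backward(dh_out: np.ndarray, cache: dict, Wx: np.ndarray, Wh: np.ndarray):
    """Backprop-through-time; returns (dx, dWx, dWh, db)."""
    x = cache["x"]
    T, B, d = x.shape
    H = HIDDEN
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dx = np.empty((T, B, d))
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        i, f, g, o = cache["i"][t], cache["f"][t], cache["g"][t], cache["o"][t]
        tc = cache["tanh_c"][t]
        dh = dh_out[t] + dh_next
        do = dh * tc
        dc = dc_next + dh * o * (1.0 - tc * tc)
        di = dc * g
        df = dc * cache["c_prev"][t]
        dg = dc * i
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
            axis=1,
        )
        dWx += x[t].T @ dz
        dWh += cache["h_prev"][t].T @ dz
        db += dz.sum(axis=0)
        dx[t] = dz @ Wx.T
        dh_next = dz @ Wh.T
        dc_next = dc * f
    return dx, dWx, dWh, db


class DeepRiskNetwork:
    """Parameter container + forward/backward for one model variant.

    Parameters live in ``self.params`` (name -> float64 array); gradients come
    back in the same keyed structure.  The SNP->gene weight matrix is stored
    dense with a boolean mask fixing its sparsity pattern; masked entries are
    zero at init and every gradient is masked, so they stay exactly zero.
    """

    def __init__(
        self,
        conn: ConnectivityMap,
        input_dim: int,
        use_partial: bool,
        covariate_dim: int,
        seed: int,
    ):
        self.conn = conn
        self.input_dim = input_dim
        self.use_partial = use_partial
        self.covariate_dim = covariate_dim
        self.chroms = sorted(conn.groups)
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}

        m = conn.n_snps
        if use_partial:
            G = conn.n_genes
            mask = np.zeros((m * input_dim, G), dtype=bool)
            col = 0
            self.gene_slices: dict[int, slice] = {}
            for c in self.chroms:
                grp = conn.groups[c]
                start = col
                for snps in grp.snp_indices:
                    for s in snps:
                        mask[s * input_dim:(s + 1) * input_dim, col] = True
                    col += 1
                self.gene_slices[c] = slice(start, col)
            self.mask = mask
            W = np.zeros((m * input_dim, G))
            fan = mask.sum(axis=0)
            for gcol in range(G):
                k = 1.0 / np.sqrt(max(fan[gcol], 1))
                W[mask[:, gcol], gcol] = rng.uniform(-k, k, size=int(fan[gcol]))
            self.params["partial_W"] = W
            self.seq_dims = {c: 1 for c in self.chroms}
            self.seq_lens = {c: len(conn.groups[c].gene_ids) for c in self.chroms}
        else:
            # sequence = SNPs of the chromosome, already in (chrom, pos) order
            self.snp_seq: dict[int, np.ndarray] = {}
            for c in self.chroms:
                grp = conn.groups[c]
                snps = sorted({s for lst in grp.snp_indices for s in lst})
                self.snp_seq[c] = np.array(snps, dtype=int)
            self.seq_dims = {c: self.input_dim for c in self.chroms}
            self.seq_lens = {c: len(self.snp_seq[c]) for c in self.chroms}

        for c in self.chroms:
            d = self.seq_dims[c]
            for direction in ("fw", "bw"):
                kx = 1.0 / np.sqrt(max(d, 1))
                kh = 1.0 / np.sqrt(HIDDEN)
                self.params[f"lstm{c}_{direction}_Wx"] = rng.uniform(-kx, kx, (d, 4 * HIDDEN))
                self.params[f"lstm{c}_{direction}_Wh"] = rng.uniform(-kh, kh, (HIDDEN, 4 * HIDDEN))
                b = np.zeros(4 * HIDDEN)
                b[HIDDEN:2 * HIDDEN] = 1.0  # forget-gate bias
                self.params[f"lstm{c}_{direction}_b"] = b

        self.h_dim = sum(self.seq_lens[c] * 2 * HIDDEN for c in self.chroms)
        D = self.h_dim + covariate_dim
        kw = 1.0 / np.sqrt(max(D, 1))
        self.params["head_w"] = rng.uniform(-kw, kw, D)
        self.params["head_b"] = np.zeros(1)

    # -- forward ---------------------------------------------------------------

    def _sequences(self, X: np.ndarray) -> dict[int, np.ndarray]:
        """X: (B, m, d) encoded genotypes -> per-chromosome (T, B, d_in) sequences."""
        B = X.shape[0]
        seqs: dict[int, np.ndarray] = {}
        if self.use_partial:
            Xf = X.reshape(B, -1)
            F_gene = Xf @ (self.params["partial_W"] * self.mask)  # (B, G)
            self._fwd_Xf = Xf
            for c in self.chroms:
                sl = self.gene_slices[c]
                seqs[c] = F_gene[:, sl].T[:, :, None]  # (T, B, 1)
        else:
            for c in self.chroms:
                seqs[c] = X[:, self.snp_seq[c], :].transpose(1, 0, 2)
        return seqs

    def forward(
        self,
        X: np.ndarray,
        covariates: np.ndarray | None = None,
        dropout_rate: float = 0.0,
        rng: np.random.Generator | None = None,
    ):
        """Return (probabilities, logits, cache)."""
        B = X.shape[0]
        seqs = self._sequences(X)
        caches: dict = {}
        h_parts = []
        for c in self.chroms:
            x = seqs[c]
            hf, cf = _lstm_forward(
                x, self.params[f"lstm{c}_fw_Wx"], self.params[f"lstm{c}_fw_Wh"],
                self.params[f"lstm{c}_fw_b"],
            )
            hb_rev, cb = _lstm_forward(
                x[::-1], self.params[f"lstm{c}_bw_Wx"], self.params[f"lstm{c}_bw_Wh"],
                self.params[f"lstm{c}_bw_b"],
            )
            hb = hb_rev[::-1]  # align backward states with forward positions
            T = x.shape[0]
            # (B, T, 2H) -> flatten steps: [h_fw_t, h_bw_t] per step
            hcat = np.concatenate([hf, hb], axis=2).transpose(1, 0, 2).reshape(B, T * 2 * HIDDEN)
            h_parts.append(hcat)
            caches[c] = (cf, cb, T)
        H_all = np.concatenate(h_parts, axis=1)  # (B, h_dim)

        if dropout_rate > 0.0:
            if rng is None:
                raise ValueError("dropout requires an rng")
            keep = (rng.random(H_all.shape) >= dropout_rate) / (1.0 - dropout_rate)
            H_drop = H_all * keep
        else:
            keep = None
            H_drop = H_all

        A = H_drop if covariates is None else np.concatenate([H_drop, covariates], axis=1)
        logits = A @ self.params["head_w"] + self.params["head_b"][0]
        probs = sigmoid(logits)
        cache = {"caches": caches, "A": A, "keep": keep, "B": B}
        return probs, logits, cache

    # -- backward --------------------------------------------------------------

    def backward(self, cache: dict, dlogit: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the loss w.r.t. every parameter, given dL/dlogit."""
        grads: dict[str, np.ndarray] = {}
        A = cache["A"]
        grads["head_w"] = A.T @ dlogit
        grads["head_b"] = np.array([dlogit.sum()])
        dA = np.outer(dlogit, self.params["head_w"])
        dH = dA[:, : self.h_dim]
        if cache["keep"] is not None:
            dH = dH * cache["keep"]

        B = cache["B"]
        offset = 0
        dF_gene_cols = []
        for c in self.chroms:
            cf, cb, T = cache["caches"][c]
            width = T * 2 * HIDDEN
            dh_c = dH[:, offset:offset + width].reshape(B, T, 2 * HIDDEN).transpose(1, 0, 2)
            offset += width
            dhf = dh_c[:, :, :HIDDEN]
            dhb = dh_c[:, :, HIDDEN:]
            dx_f, dWx_f, dWh_f, db_f = _lstm_backward(
                dhf, cf, self.params[f"lstm{c}_fw_Wx"], self.params[f"lstm{c}_fw_Wh"]
            )
            dx_b_rev, dWx_b, dWh_b, db_b = _lstm_backward(
                dhb[::-1], cb, self.params[f"lstm{c}_bw_Wx"], self.params[f"lstm{c}_bw_Wh"]
            )
            grads[f"lstm{c}_fw_Wx"], grads[f"lstm{c}_fw_Wh"], grads[f"lstm{c}_fw_b"] = (
                dWx_f, dWh_f, db_f,
            )
            grads[f"lstm{c}_bw_Wx"], grads[f"lstm{c}_bw_Wh"], grads[f"lstm{c}_bw_b"] = (
                dWx_b, dWh_b, db_b,
            )
            if self.use_partial:
                dx = dx_f + dx_b_rev[::-1]  # (T, B, 1)
                dF_gene_cols.append(dx[:, :, 0].T)  # (B, T)
        if self.use_partial:
            dF_gene = np.concatenate(dF_gene_cols, axis=1)  # (B, G)
            grads["partial_W"] = (self._fwd_Xf.T @ dF_gene) * self.mask
        return grads

    def l2_value_and_grads(self, coef: float, grads: dict[str, np.ndarray]) -> float:
        """Add L2 gradients on BiLSTM weight matrices in place; return penalty value."""
        penalty = 0.0
        if coef == 0.0:
            return 0.0
        for name, p in self.params.items():
            if "_Wx" in name or "_Wh" in name:
                penalty += coef * float((p * p).sum())
                grads[name] = grads.get(name, 0.0) + 2.0 * coef * p
        return penalty

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = params[k].copy()


class Adam:
    """Adam optimizer over a keyed parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * (g * g)
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
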