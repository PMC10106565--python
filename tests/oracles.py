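"""Independent brute-force reference implementations used only by tests.

Every function here is written as plain loops, directly transcribing the
defining formulas, and never calls into the package's vectorized paths.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------- convolution
def conv2d_loop(x, w, b=None, stride=1, padding=0, dilation=1):
    """y[i] = sum_l x[i + d*l] w[l], looped over every output position."""
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    B, C, H, W = x.shape
    F, _, KH, KW = w.shape
    xp = np.zeros((B, C, H + 2 * padding, W + 2 * padding))
    xp[:, :, padding:padding + H, padding:padding + W] = x
    OH = (xp.shape[2] - (KH - 1) * dilation - 1) // stride + 1
    OW = (xp.shape[3] - (KW - 1) * dilation - 1) // stride + 1
    out = np.zeros((B, F, OH, OW))
    for bi in range(B):
        for f in range(F):
            for i in range(OH):
                for j in range(OW):
                    acc = 0.0
                    for c in range(C):
                        for k in range(KH):
                            for l in range(KW):
                                acc += xp[bi, c, i * stride + k * dilation,
                                          j * stride + l * dilation] * w[f, c, k, l]
                    out[bi, f, i, j] = acc + (0.0 if b is None else b[f])
    return out


# ------------------------------------------------------------------ attention
def attention_loop(q, k, v):
    """softmax(Q K^T / sqrt(d_k)) V computed elementwise."""
    q, k, v = (np.asarray(a, dtype=np.float64) for a in (q, k, v))
    nq, dk = q.shape
    nk = k.shape[0]
    out = np.zeros((nq, v.shape[1]))
    for i in range(nq):
        scores = np.array([sum(q[i, t] * k[j, t] for t in range(dk)) / math.sqrt(dk)
                           for j in range(nk)])
        e = np.exp(scores - scores.max())
        wgt = e / e.sum()
        for m in range(v.shape[1]):
            out[i, m] = sum(wgt[j] * v[j, m] for j in range(nk))
    return out


def msa_loop(x, wq, wk, wv, wo, bq, bk, bv, bo, n_heads):
    """Per-head loop: h_i = Attention(Q Wq_i, K Wk_i, V Wv_i); concat; W^O."""
    x = np.asarray(x, dtype=np.float64)
    N, K = x.shape
    d = K // n_heads
    q_all = x @ wq + bq
    k_all = x @ wk + bk
    v_all = x @ wv + bv
    heads = []
    for h in range(n_heads):
        sl = slice(h * d, (h + 1) * d)
        heads.append(attention_loop(q_all[:, sl], k_all[:, sl], v_all[:, sl]))
    concat = np.concatenate(heads, axis=1)
    return concat @ wo + bo


def layer_norm_loop(x, gamma, beta, eps=1e-6):
    x = np.asarray(x, dtype=np.float64)
    out = np.zeros_like(x)
    flat = x.reshape(-1, x.shape[-1])
    oflat = out.reshape(-1, x.shape[-1])
    for i in range(flat.shape[0]):
        row = flat[i]
        mu = row.mean()
        var = ((row - mu) ** 2).mean()
        oflat[i] = gamma * (row - mu) / math.sqrt(var + eps) + beta
    return out


def mlp_loop(x, w1, b1, w2, b2):
    h = np.maximum(np.asarray(x, dtype=np.float64) @ w1 + b1, 0.0)
    return h @ w2 + b2


# ------------------------------------------------------------- attention gate
def attention_gate_loop(x, c, wx, bx, wc, bc, wpsi, bpsi):
    """sigmoid(psi(relu(Wx X + Wc C))) * C with 1x1 convolutions as loops."""
    x = np.asarray(x, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)
    B, CX, H, W = x.shape
    CC = c.shape[1]
    inter = wx.shape[0]
    out = np.zeros_like(c)
    for bi in range(B):
        for i in range(H):
            for j in range(W):
                pre = np.zeros(inter)
                for m in range(inter):
                    pre[m] = (sum(wx[m, t] * x[bi, t, i, j] for t in range(CX)) + bx[m]
                              + sum(wc[m, t] * c[bi, t, i, j] for t in range(CC)) + bc[m])
                act = np.maximum(pre, 0.0)
                z = sum(wpsi[0, t] * act[t] for t in range(inter)) + bpsi[0]
                gate = 1.0 / (1.0 + math.exp(-z))
                out[bi, :, i, j] = gate * c[bi, :, i, j]
    return out


# ----------------------------------------------------------------------- SSIM
def ssim_sliding(p, g, kernel, c1=0.01 ** 2, c2=0.03 ** 2):
    """Mean windowed SSIM over all valid window positions (loops)."""
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    kh, kw = kernel.shape
    H, W = p.shape
    vals = []
    for i in range(H - kh + 1):
        for j in range(W - kw + 1):
            wp = p[i:i + kh, j:j + kw]
            wg = g[i:i + kh, j:j + kw]
            mp = (kernel * wp).sum()
            mg = (kernel * wg).sum()
            vp = (kernel * wp * wp).sum() - mp * mp
            vg = (kernel * wg * wg).sum() - mg * mg
            cov = (kernel * wp * wg).sum() - mp * mg
            num = (2 * mp * mg + c1) * (2 * cov + c2)
            den = (mp * mp + mg * mg + c1) * (vp + vg + c2)
            vals.append(num / den)
    return float(np.mean(vals))


def laplacian_loop(img):
    """5-point Laplacian with replicate borders, looped."""
    img = np.asarray(img, dtype=np.float64)
    H, W = img.shape
    out = np.zeros_like(img)
    for i in range(H):
        for j in range(W):
            up = img[max(i - 1, 0), j]
            dn = img[min(i + 1, H - 1), j]
            lf = img[i, max(j - 1, 0)]
            rt = img[i, min(j + 1, W - 1)]
            out[i, j] = up + dn + lf + rt - 4 * img[i, j]
    return out


# -------------------------------------------------------------------- metrics
def dice_iou_counts(p, g):
    """Set counting over explicit pixel sets."""
    pset = {tuple(idx) for idx in np.argwhere(np.asarray(p) == 1)}
    gset = {tuple(idx) for idx in np.argwhere(np.asarray(g) == 1)}
    inter = len(pset & gset)
    union = len(pset | gset)
    if not pset and not gset:
        return 1.0, 1.0
    return 2.0 * inter / (len(pset) + len(gset)), inter / union


def _dist_to_fg_brute(g):
    """Euclidean distance and index of the nearest foreground pixel."""
    g = np.asarray(g, dtype=bool)
    H, W = g.shape
    fg = np.argwhere(g)
    dst = np.zeros((H, W))
    nearest = np.zeros((H, W, 2), dtype=int)
    for i in range(H):
        for j in range(W):
            d2 = ((fg[:, 0] - i) ** 2 + (fg[:, 1] - j) ** 2)
            a = int(np.argmin(d2))
            dst[i, j] = math.sqrt(float(d2[a]))
            nearest[i, j] = fg[a]
    return dst, nearest


def _gauss7x7(sigma=5.0):
    k = np.zeros((7, 7))
    for i in range(7):
        for j in range(7):
            k[i, j] = math.exp(-((i - 3) ** 2 + (j - 3) ** 2) / (2 * sigma ** 2))
    return k / k.sum()


def wfm_reference(pred, gt, beta=1.0):
    """Step-by-step weighted F-beta (error propagation + distance weighting)."""
    fg = np.asarray(pred, dtype=np.float64)
    g = np.asarray(gt, dtype=bool)
    H, W = g.shape
    if not g.any():
        return 1.0 if fg.max() == 0 else 0.0
    e = np.abs(fg - g.astype(float))
    dst, nearest = _dist_to_fg_brute(g)
    et = e.copy()
    for i in range(H):
        for j in range(W):
            if not g[i, j]:
                ni, nj = nearest[i, j]
                et[i, j] = e[ni, nj]
    k = _gauss7x7()
    ea = np.zeros_like(et)
    for i in range(H):
        for j in range(W):
            acc = 0.0
            for a in range(-3, 4):
                for b in range(-3, 4):
                    ii, jj = i + a, j + b
                    if 0 <= ii < H and 0 <= jj < W:
                        acc += et[ii, jj] * k[a + 3, b + 3]
            ea[i, j] = acc
    min_e_ea = e.copy()
    for i in range(H):
        for j in range(W):
            if g[i, j] and ea[i, j] < e[i, j]:
                min_e_ea[i, j] = ea[i, j]
    b_w = np.ones((H, W))
    for i in range(H):
        for j in range(W):
            if not g[i, j]:
                b_w[i, j] = 2.0 - math.exp(math.log(0.5) / 5.0 * dst[i, j])
    ew = min_e_ea * b_w
    eps = np.finfo(float).eps
    tpw = g.sum() - ew[g].sum()
    fpw = ew[~g].sum()
    r = 1.0 - ew[g].mean()
    p = tpw / (tpw + fpw + eps)
    q = (1 + beta ** 2) * r * p / (r + beta ** 2 * p + eps)
    return float(min(max(q, 0.0), 1.0))


def _region_ssim_ref(p, g):
    n = p.size
    eps = np.finfo(float).eps
    if n <= 1:
        return 1.0 if p.size and float(p.flat[0]) == float(g.flat[0]) else 0.0
    x = float(np.mean(p))
    y = float(np.mean(g))
    sx = float(((p - x) ** 2).sum() / (n - 1))
    sy = float(((g - y) ** 2).sum() / (n - 1))
    sxy = float(((p - x) * (g - y)).sum() / (n - 1))
    a = 4 * x * y * sxy
    b = (x * x + y * y) * (sx + sy)
    if a != 0:
        return a / (b + eps)
    return 1.0 if b == 0 else 0.0


def sm_reference(pred, gt):
    """Structure measure: 0.5 object-aware + 0.5 region-aware similarity."""
    fg = np.asarray(pred, dtype=np.float64)
    g = np.asarray(gt, dtype=bool)
    eps = np.finfo(float).eps
    mu = g.mean()
    if mu == 0:
        return 1.0 - fg.mean()
    if mu == 1:
        return fg.mean()

    def obj(vals):
        if vals.size == 0:
            return 0.0
        m, s = vals.mean(), vals.std()
        return 2.0 * m / (m * m + 1.0 + 2.0 * s + eps)

    s_o = mu * obj(fg[g]) + (1 - mu) * obj((1.0 - fg)[~g])
    rows, cols = np.nonzero(g)
    cy, cx = int(round(rows.mean())), int(round(cols.mean()))
    H, W = g.shape
    blocks = [((0, cy + 1), (0, cx + 1)), ((0, cy + 1), (cx + 1, W)),
              ((cy + 1, H), (0, cx + 1)), ((cy + 1, H), (cx + 1, W))]
    s_r = 0.0
    for (r0, r1), (c0, c1) in blocks:
        gb = g[r0:r1, c0:c1].astype(float)
        pb = fg[r0:r1, c0:c1]
        s_r += (gb.size / g.size) * _region_ssim_ref(pb, gb)
    return float(min(max(0.5 * s_o + 0.5 * s_r, 0.0), 1.0))


def em_reference(pred, gt):
    """Enhanced-alignment measure via a pixelwise loop."""
    p = np.asarray(pred, dtype=np.float64)
    g = np.asarray(gt, dtype=np.float64)
    H, W = g.shape
    eps = np.finfo(float).eps
    if g.sum() == 0:
        enhanced = 1.0 - p
    elif g.sum() == g.size:
        enhanced = p.copy()
    else:
        mg, mp = g.mean(), p.mean()
        enhanced = np.zeros((H, W))
        for i in range(H):
            for j in range(W):
                a = g[i, j] - mg
                b = p[i, j] - mp
                align = 2 * a * b / (a * a + b * b + eps)
                enhanced[i, j] = (align + 1.0) ** 2 / 4.0
    return float(min(max(enhanced.sum() / (H * W - 1 + eps), 0.0), 1.0))


def bilinear_resize_loop(img, out_h, out_w):
    """Pixel-center-aligned bilinear resize of a 2-D array, looped."""
    img = np.asarray(img, dtype=np.float64)
    H, W = img.shape
    out = np.zeros((out_h, out_w))
    for i in range(out_h):
        sy = min(max((i + 0.5) * H / out_h - 0.5, 0), H - 1)
        y0 = int(math.floor(sy))
        y1 = min(y0 + 1, H - 1)
        wy = sy - y0
        for j in range(out_w):
            sx = min(max((j + 0.5) * W / out_w - 0.5, 0), W - 1)
            x0 = int(math.floor(sx))
            x1 = min(x0 + 1, W - 1)
            wx = sx - x0
            out[i, j] = ((1 - wy) * (1 - wx) * img[y0, x0]
                         + (1 - wy) * wx * img[y0, x1]
                         + wy * (1 - wx) * img[y1, x0]
                         + wy * wx * img[y1, x1])
    return out


def maxpool_loop(img, size):
    img = np.asarray(img, dtype=np.float64)
    H, W = img.shape
    out = np.zeros((H // size, W // size))
    for i in range(H // size):
        for j in range(W // size):
            out[i, j] = img[i * size:(i + 1) * size, j * size:(j + 1) * size].max()
    return out
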