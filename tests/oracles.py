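"""Explicit-loop reference implementations of the attention blocks and loss.

Deliberately independent of the package's compute layer: plain numpy,
scalar loops, no autodiff.  Used to pin down the semantics of every
block on tiny instances.
"""

import numpy as np


def mlp2(x, w1, b1, w2, b2):
    """Two affine maps with a rectifier, applied to a 1-D descriptor."""
    h = np.maximum(w1 @ x + b1, 0.0)
    return w2 @ h + b2


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


def channel_attention(f, w1, b1, w2, b2):
    """Per-channel weights from shared-MLP avg/max descriptors."""
    C = f.shape[0]
    avg = np.array([f[c].mean() for c in range(C)])
    mx = np.array([f[c].max() for c in range(C)])
    w = sigmoid(mlp2(avg, w1, b1, w2, b2) + mlp2(mx, w1, b1, w2, b2))
    out = np.empty_like(f, dtype=np.float64)
    for c in range(C):
        out[c] = w[c] * f[c]
    return out


def axis_attention(f_c, axis, kernel_weight, branch_scale):
    """Slice attention along spatial axis index 1/2/3 of (C, D, H, W)."""
    k = kernel_weight.shape[0]
    pad = (k - 1) // 2
    A = f_c.shape[axis]
    other = tuple(i for i in range(4) if i != axis)
    avg = f_c.mean(axis=other)
    mx = f_c.max(axis=other)
    desc = np.zeros((2, A + 2 * pad))
    desc[0, pad:pad + A] = avg
    desc[1, pad:pad + A] = mx
    for s, vals in ((0, avg), (1, mx)):      # replicate-padded edges
        desc[s, :pad] = vals[0]
        desc[s, pad + A:] = vals[-1]
    logits = np.zeros(A)
    for a in range(A):
        for x in range(k):
            for s in range(2):
                logits[a] += kernel_weight[x, s] * desc[s, a + x]
    w = sigmoid(logits)
    out = np.empty_like(f_c, dtype=np.float64)
    for a in range(A):
        sl = [slice(None)] * 4
        sl[axis] = a
        out[tuple(sl)] = branch_scale * w[a] * f_c[tuple(sl)]
    return out


def smwa(f, ch_params, axis_params):
    """ch_params = (w1,b1,w2,b2); axis_params = [(kernel, scale)] * 3."""
    f_c = channel_attention(f, *ch_params)
    total = np.zeros_like(f_c)
    for axis, (kw, scale) in zip((1, 2, 3), axis_params):
        total += axis_attention(f_c, axis, kw, scale)
    return total


def conv3d(x, w, b=None, padding=0, dilation=1):
    """Naive quadruple-loop 3D cross-correlation, stride 1."""
    cout, cin, k = w.shape[0], w.shape[1], w.shape[2]
    p, dl = padding, dilation
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    oD = x.shape[1] + 2 * p - dl * (k - 1)
    oH = x.shape[2] + 2 * p - dl * (k - 1)
    oW = x.shape[3] + 2 * p - dl * (k - 1)
    out = np.zeros((cout, oD, oH, oW))
    for co in range(cout):
        for z in range(oD):
            for y in range(oH):
                for xx in range(oW):
                    acc = 0.0
                    for ci in range(cin):
                        for kz in range(k):
                            for ky in range(k):
                                for kx in range(k):
                                    acc += w[co, ci, kz, ky, kx] * \
                                        xp[ci, z + kz * dl, y + ky * dl, xx + kx * dl]
                    out[co, z, y, xx] = acc + (b[co] if b is not None else 0.0)
    return out


def adaptive_maxpool(x, bins):
    """Adaptive max pooling with floor/ceil window boundaries."""
    C = x.shape[0]
    spatial = x.shape[1:]
    bins = tuple(min(b, s) for b, s in zip(bins, spatial))
    out = np.zeros((C,) + bins)
    for c in range(C):
        for iz in range(bins[0]):
            z0, z1 = int(np.floor(iz * spatial[0] / bins[0])), int(np.ceil((iz + 1) * spatial[0] / bins[0]))
            for iy in range(bins[1]):
                y0, y1 = int(np.floor(iy * spatial[1] / bins[1])), int(np.ceil((iy + 1) * spatial[1] / bins[1]))
                for ix in range(bins[2]):
                    x0, x1 = int(np.floor(ix * spatial[2] / bins[2])), int(np.ceil((ix + 1) * spatial[2] / bins[2]))
                    out[c, iz, iy, ix] = x[c, z0:z1, y0:y1, x0:x1].max()
    return out


def cascaded_pyramid_pool(q, bins):
    cols = []
    current = q
    for b in bins:
        current = adaptive_maxpool(current, (b, b, b))
        cols.append(current.reshape(q.shape[0], -1))
    return np.concatenate(cols, axis=1)


def context_affinity(q, k, cosine=True, eps=1e-8):
    """Per-pixel softmax over cosine similarities; explicit loops."""
    cprime = q.shape[0]
    qf = q.reshape(cprime, -1).T          # (N, C')
    N, M = qf.shape[0], k.shape[1]
    a = np.zeros((N, M))
    for i in range(N):
        qi = qf[i]
        sims = np.zeros(M)
        for j in range(M):
            kj = k[:, j]
            if cosine:
                sims[j] = (qi / (np.linalg.norm(qi) + eps)) @ (kj / (np.linalg.norm(kj) + eps))
            else:
                sims[j] = qi @ kj
        e = np.exp(sims - sims.max())
        a[i] = e / e.sum()
    return a


def aggregate_context(v, a, spatial):
    C, M = v.shape
    N = a.shape[0]
    e = np.zeros((C, N))
    for i in range(N):
        for j in range(M):
            e[:, i] += a[i, j] * v[:, j]
    return e.reshape((C,) + tuple(spatial))


def cfc(x, params):
    """Full calibration oracle.

    ``params`` carries the raw arrays: reduce (w, b) for the 1x1x1 conv,
    key (w, b), value (w, b) linear maps, crb1 (w, b) 1x1x1 conv,
    crb2 (w, b) 3x3x3 conv, bins, cosine.
    """
    q = conv3d(x, params["reduce_w"], params["reduce_b"])
    z = cascaded_pyramid_pool(q, params["bins"])
    k = params["key_w"] @ z + params["key_b"][:, None]
    v = params["value_w"] @ z + params["value_b"][:, None]
    a = context_affinity(q, k, cosine=params["cosine"])
    e = aggregate_context(v, a, x.shape[1:])
    gate = np.tanh(conv3d(conv3d(x + e, params["crb1_w"], params["crb1_b"]),
                          params["crb2_w"], params["crb2_b"], padding=1))
    e_prime = gate * e + e
    return x + e_prime


def gate_fuse(skip, up, w1, b1, w2, b2):
    cat = np.concatenate([skip, up], axis=0)
    desc = np.array([cat[c].mean() for c in range(cat.shape[0])])
    g = sigmoid(mlp2(desc, w1, b1, w2, b2))
    out = np.empty_like(cat)
    for c in range(cat.shape[0]):
        out[c] = g[c] * cat[c]
    return out


def combined_loss(pred, target, alpha=1.0, beta=0.5, dice_eps=1e-5, bce_eps=1e-7):
    """Scalar-loop BCE + Dice over region channels."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    bce_terms = []
    for p, t in zip(pred.ravel(), target.ravel()):
        p = min(max(p, bce_eps), 1.0 - bce_eps)
        bce_terms.append(-(t * np.log(p) + (1 - t) * np.log(1 - p)))
    bce = float(np.mean(bce_terms))
    dice_losses = []
    for r in range(pred.shape[0]):
        inter = float((pred[r] * target[r]).sum())
        denom = float(pred[r].sum() + target[r].sum())
        dice_losses.append(1.0 - (2 * inter + dice_eps) / (denom + dice_eps))
    return alpha * bce + beta * float(np.mean(dice_losses))


# -- parameter extraction helpers (bridge package modules -> raw arrays) -----

def channel_params(block):
    return (block.mlp.fc1.weight.data, block.mlp.fc1.bias.data,
            block.mlp.fc2.weight.data, block.mlp.fc2.bias.data)


def axis_params(block):
    return (block.kernel_weight.data, float(block.branch_scale.data))


def smwa_params(block):
    return channel_params(block.channel), [axis_params(b) for b in
                                           (block.axis_d, block.axis_h, block.axis_w)]


def cfc_params(block):
    return {
        "reduce_w": block.reduce_conv.weight.data, "reduce_b": block.reduce_conv.bias.data,
        "key_w": block.key_proj.weight.data, "key_b": block.key_proj.bias.data,
        "value_w": block.value_proj.weight.data, "value_b": block.value_proj.bias.data,
        "crb1_w": block.crb_w1.weight.data, "crb1_b": block.crb_w1.bias.data,
        "crb2_w": block.crb_w2.weight.data, "crb2_b": block.crb_w2.bias.data,
        "bins": block.pyramid_bins, "cosine": block.cosine,
    }


def gate_params(block):
    return (block.mlp.fc1.weight.data, block.mlp.fc1.bias.data,
            block.mlp.fc2.weight.data, block.mlp.fc2.bias.data)
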