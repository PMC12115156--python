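"""Fore-background contrast attention, SCAM, BottleRep and CEM."""

import numpy as np
import pytest

from seanet import tensor as T
from seanet.attention import CEM, FBC, SCAM, BottleRep
from seanet.tensor import Tensor, sigmoid_np


def _fbc_loop_oracle(fbc: FBC, x: np.ndarray) -> np.ndarray:
    """Nested-loop evaluation of the fore/background gating equations.

    No matrix algebra: every pooled descriptor, gate and output pixel is
    accumulated with explicit python loops from the block's own weights.
    """
    B, C, H, W = x.shape
    conv = fbc.cblr.mods[0]
    bn = fbc.cblr.mods[1]
    out = np.zeros_like(x, dtype=np.float64)
    wf = fbc.rho_f.weight.data[:, :, 0, 0]
    bf = fbc.rho_f.bias.data
    wb = fbc.rho_b.weight.data[:, :, 0, 0]
    bb = fbc.rho_b.bias.data
    for b in range(B):
        ff = np.zeros((H, W))
        for i in range(H):
            for j in range(W):
                z = conv.bias.data[0]
                for c in range(C):
                    z += conv.weight.data[0, c, 0, 0] * x[b, c, i, j]
                z = (z - bn.running_mean[0]) / np.sqrt(bn.running_var[0] + bn.eps)
                z = z * bn.weight.data[0] + bn.bias.data[0]
                z = z if z > 0 else 0.1 * z          # leaky rectifier
                ff[i, j] = 1.0 / (1.0 + np.exp(-z))  # sigmoid -> foreground map
        fb = 1.0 - ff
        vf = np.zeros(C)
        vb = np.zeros(C)
        for c in range(C):
            for i in range(H):
                for j in range(W):
                    vf[c] += ff[i, j] * x[b, c, i, j]
                    vb[c] += fb[i, j] * x[b, c, i, j]
        cf = np.zeros(C)
        cb = np.zeros(C)
        for c in range(C):
            zf, zb = bf[c], bb[c]
            for c2 in range(C):
                zf += wf[c, c2] * vf[c2]
                zb += wb[c, c2] * vb[c2]
            cf[c] = 1.0 / (1.0 + np.exp(-zf))
            cb[c] = 1.0 / (1.0 + np.exp(-zb))
        for c in range(C):
            for i in range(H):
                for j in range(W):
                    out[b, c, i, j] = x[b, c, i, j] * (cf[c] - cb[c])
    return out


@pytest.mark.parametrize("seed", range(5))
def test_fbc_matches_nested_loop_oracle(seed):
    rng = np.random.default_rng(seed)
    B, C, H = rng.integers(1, 3), int(rng.integers(2, 5)), int(rng.integers(2, 5))
    fbc = FBC(C, rng=rng).eval()
    x = rng.normal(size=(B, C, H, H)).astype(np.float32)
    out = fbc(Tensor(x)).data
    ref = _fbc_loop_oracle(fbc, x)
    assert np.abs(out - ref).max() < 1e-5


def test_activation_maps_are_complementary(rng):
    fbc = FBC(4, rng=rng).eval()
    x = Tensor(rng.normal(size=(2, 4, 5, 5)).astype(np.float32))
    ff, fb = fbc.activation_maps(x)
    assert ff.data.shape == (2, 1, 5, 5)
    assert (ff.data > 0).all() and (ff.data < 1).all()
    assert np.abs(ff.data + fb.data - 1.0).max() < 1e-6


def test_pooled_descriptors_have_channel_shape(rng):
    fbc = FBC(8, rng=rng).eval()
    x = Tensor(rng.normal(size=(2, 8, 4, 4)).astype(np.float32))
    vf, vb, cf, cb = fbc.descriptors(x)
    assert vf.data.shape == vb.data.shape == (2, 1, 8)
    assert cf.data.shape == cb.data.shape == (2, 1, 8)
    assert (cf.data > 0).all() and (cf.data < 1).all()
    assert (cb.data > 0).all() and (cb.data < 1).all()


def test_symmetric_gates_yield_exact_zero_map(rng):
    """With tied gates and a zero pre-activation map, foreground equals
    background everywhere, the gate difference vanishes, and the output
    is identically zero."""
    fbc = FBC(4, shared_gate=True, rng=rng).eval()
    conv = fbc.cblr.mods[0]
    conv.weight.data[:] = 0.0
    conv.bias.data[:] = 0.0
    x = Tensor(rng.normal(size=(2, 4, 3, 3)).astype(np.float32))
    out = fbc(x)
    assert np.abs(out.data).max() == 0.0


def test_fbc_width_mismatch_and_empty_input_rejected(rng):
    fbc = FBC(4, rng=rng)
    with pytest.raises(ValueError):
        fbc(Tensor(np.zeros((1, 5, 3, 3), dtype=np.float32)))
    with pytest.raises(ValueError):
        fbc(Tensor(np.zeros((1, 4, 0, 3), dtype=np.float32)))


def test_scam_shape_and_identity_limit(rng):
    scam = SCAM(16, rng=rng).eval()
    x = rng.normal(size=(2, 16, 8, 8)).astype(np.float32)
    out = scam(Tensor(x))
    assert out.data.shape == (2, 16, 8, 8)
    # saturate both attention stages -> gates ~ 1 -> output ~ input
    scam.fc1.weight.data[:] = 0.0
    scam.fc1.bias.data[:] = 10.0
    scam.fc2.weight.data[:] = 10.0
    scam.fc2.bias.data[:] = 100.0
    scam.spatial.weight.data[:] = 0.0
    scam.spatial.bias.data[:] = 100.0
    out = scam(Tensor(x))
    assert np.abs(out.data - x).max() < 1e-4


def test_scam_channel_gate_constant_map_equals_pooled(rng):
    """On a per-channel-constant input, the gate equals the gate of its
    1x1 pooled version (pooling a constant is the constant)."""
    scam = SCAM(6, rng=rng).eval()
    const = rng.normal(size=(1, 6, 1, 1)).astype(np.float32)
    x = np.broadcast_to(const, (1, 6, 7, 7)).copy()
    g_full = scam.channel_gate(Tensor(x)).data
    g_pooled = scam.channel_gate(Tensor(const.copy())).data
    assert np.allclose(g_full, g_pooled, atol=1e-6)


def test_bottlerep_zero_and_identity_paths(rng):
    blk = BottleRep(8, 8, rng=rng).eval()
    zero = Tensor(np.zeros((1, 8, 5, 5), dtype=np.float32))
    assert np.allclose(blk(zero).data, 0.0)
    # zero the conv path; shortcut weight 1 -> identity
    for conv in (blk.conv1.mods[0], blk.conv2.mods[0]):
        conv.weight.data[:] = 0.0
    x = rng.normal(size=(1, 8, 5, 5)).astype(np.float32)
    assert np.allclose(blk(Tensor(x)).data, x, atol=1e-6)


def test_bottlerep_matches_manual_composition(rng):
    blk = BottleRep(8, 8, rng=rng).eval()
    x = Tensor(rng.normal(size=(1, 8, 5, 5)).astype(np.float32))
    manual = blk.conv2(blk.conv1(x)).data + blk.alpha.data * x.data
    assert np.allclose(blk(x).data, manual, atol=1e-6)


def test_cem_collects_one_fbc_branch_plus_three_bottlereps(rng):
    cem = CEM(32, 32, hidden=16, rng=rng).eval()
    assert len(cem.reps) == 3
    assert cem.cbs3.mods[0].weight.data.shape[1] == 4 * 16
    x = Tensor(rng.normal(size=(2, 32, 16, 16)).astype(np.float32))
    out = cem(x)
    assert out.data.shape == (2, 32, 16, 16)


def test_cem_matches_manual_trace(rng):
    cem = CEM(16, 16, hidden=8, rng=rng).eval()
    x = Tensor(rng.normal(size=(1, 16, 8, 8)).astype(np.float32))
    xs = cem.scam(x)
    y1 = cem.cbs1(xs)
    y1 = cem.fbc(y1) + y1
    y2 = cem.cbs2(xs)
    mid = [y1]
    for rep in cem.reps:
        y2 = rep(y2)
        mid.append(y2)
    ref = cem.cbs3(T.concat(mid, axis=1)).data
    assert np.allclose(cem(x).data, ref, atol=1e-6)


def test_cem_zero_gated_fbc_reduces_to_plain_branch(rng):
    cem = CEM(16, 16, hidden=8, rng=rng).eval()
    # tie the gates and zero the foreground conv: cf == cb -> FBC output 0
    cem.fbc.rho_b.weight.data = cem.fbc.rho_f.weight.data.copy()
    cem.fbc.rho_b.bias.data = cem.fbc.rho_f.bias.data.copy()
    cem.fbc.cblr.mods[0].weight.data[:] = 0.0
    cem.fbc.cblr.mods[0].bias.data[:] = 0.0
    x = Tensor(rng.normal(size=(1, 16, 8, 8)).astype(np.float32))
    y1 = cem.cbs1(cem.scam(x))
    assert np.allclose(cem.fbc(y1).data + y1.data, y1.data, atol=1e-6)
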