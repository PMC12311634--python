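"""Geometric vector perceptron (GVP) layers on the NumPy autodiff backend.

A GVP jointly transforms scalar features s in R^ds and vector features
V in R^(dv x 3). Vector channels are mixed by channel-wise linear maps
(rotation-equivariant), their norms are fed into the scalar track
(rotation-invariant), and output vectors are modulated by a sigmoid gate
computed from the scalar track (the vector-gating variant).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, gather, segment_mean

__all__ = ["Linear", "GVP", "GVPConvLayer", "scalar_layernorm"]


def _xavier(rng, fan_in, fan_out, shape):
    return rng.normal(0.0, np.sqrt(2.0 / (fan_in + fan_out)), size=shape)


class Module:
    def params(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
        return out


class Linear(Module):
    def __init__(self, in_dim, out_dim, rng):
        self.w = Tensor(_xavier(rng, in_dim, out_dim, (in_dim, out_dim)), requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class GVP(Module):
    """(s, V) -> (s', V') with scalar ReLU and sigmoid vector gating."""

    def __init__(self, in_s, in_v, out_s, out_v, rng, scalar_act=True, vector_gate=True):
        self.in_v, self.out_v = in_v, out_v
        self.scalar_act = scalar_act
        self.vector_gate = vector_gate
        h = max(in_v, out_v) if in_v else 0
        self.h = h
        if in_v:
            self.wh = Tensor(_xavier(rng, in_v, h, (h, in_v)), requires_grad=True)
            if out_v:
                self.wmu = Tensor(_xavier(rng, h, out_v, (out_v, h)), requires_grad=True)
        self.ws = Linear(in_s + h, out_s, rng)
        if out_v and vector_gate:
            self.wg = Linear(out_s, out_v, rng)

    def __call__(self, s: Tensor, v: Tensor | None):
        if self.in_v:
            vh = v.channel_linear(self.wh)          # (n, h, 3)
            vn = vh.norm(axis=-1)                   # (n, h)
            s_in = concat([s, vn], axis=-1)
        else:
            s_in = s
        s_lin = self.ws(s_in)
        s_out = s_lin.relu() if self.scalar_act else s_lin
        v_out = None
        if self.out_v:
            vmu = vh.channel_linear(self.wmu)       # (n, out_v, 3)
            if self.vector_gate:
                gate = self.wg(s_out).sigmoid()     # (n, out_v)
                v_out = vmu * _expand_last(gate)
            else:
                v_out = vmu * _expand_last(vmu.norm(axis=-1).sigmoid())
        return s_out, v_out


def _expand_last(t: Tensor) -> Tensor:
    """(n, c) -> (n, c, 1) view as a Tensor op (reshape is linear)."""
    out = Tensor(t.data[..., None], parents=(t,))

    def bw(g):
        if t.requires_grad:
            t._accum(g[..., 0])
    out._backward = bw
    return out


def scalar_layernorm(s: Tensor, eps=1e-5) -> Tensor:
    mu = s.mean(axis=-1, keepdims=True)
    d = s - mu
    var = (d * d).mean(axis=-1, keepdims=True)
    return d * (var + eps) ** -0.5


class GVPConvLayer(Module):
    """One round of message passing with GVP messages and residual updates.

    Messages are computed from (receiver, sender, edge) features by a single
    vector-gated GVP, mean-aggregated over incoming edges, and added to the
    node state; a position-wise GVP feed-forward follows. Scalar tracks are
    layer-normalized after each residual.
    """

    def __init__(self, ns, nv, es, ev, rng):
        self.msg = GVP(2 * ns + es, 2 * nv + ev, ns, nv, rng)
        self.ff = GVP(ns, nv, ns, nv, rng)

    def __call__(self, node_s, node_v, edge_index, edge_s, edge_v):
        src, dst = edge_index
        n = node_s.shape[0]
        ms = concat([gather(node_s, dst), gather(node_s, src), edge_s], axis=-1)
        mv = concat([gather(node_v, dst), gather(node_v, src), edge_v], axis=1)
        msg_s, msg_v = self.msg(ms, mv)
        agg_s = segment_mean(msg_s, dst, n)
        agg_v = segment_mean(msg_v, dst, n)
        node_s = scalar_layernorm(node_s + agg_s)
        node_v = node_v + agg_v
        ff_s, ff_v = self.ff(node_s, node_v)
        node_s = scalar_layernorm(node_s + ff_s)
        node_v = node_v + ff_v
        return node_s, node_v
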