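"""Parameter and FLOPs accounting for a resolved network spec.

FLOPs follow the convolution multiply-accumulate sum

    FLOPs = sum_l 2 * C_in(l) * C_out(l) * K_h(l) * K_w(l) * H_out(l) * W_out(l)

counting a multiply-accumulate as 2 operations; activations, batch norm
and NMS are excluded.  Deformable layers contribute their offset-branch
convolution to the same sum; their bilinear-interpolation cost
(4 * |S| multiplies per output location per input channel) is reported
separately so the headline figure stays a pure convolution sum.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from eyolo.elastic_net import EYOLONet, LayerDef, NetworkSpec


def layer_flops(c_in: int, c_out: int, kh: int, kw: int,
                h_out: int, w_out: int) -> int:
    """2 * C_in * C_out * K_h * K_w * H_out * W_out."""
    return 2 * c_in * c_out * kh * kw * h_out * w_out


def conv_params(c_in: int, c_out: int, kh: int, kw: int,
                bias: bool = True, bn: bool = True) -> int:
    """Kernel + bias (+ 2*C_out for batch-norm scale/shift)."""
    p = c_in * c_out * kh * kw
    if bias:
        p += c_out
    if bn:
        p += 2 * c_out
    return p


@dataclasses.dataclass
class ProfileRow:
    layer: str
    c_in: int
    c_out: int
    kh: int
    kw: int
    h_out: int
    w_out: int
    flops: int
    params: int


@dataclasses.dataclass
class ModelProfile:
    """Totals plus a per-layer breakdown."""

    rows: list[ProfileRow]
    total_params: int
    total_flops: int
    deform_interp_flops: int  # bilinear-sampling multiplies, outside Eq-14 sum

    @property
    def total_flops_with_interp(self) -> int:
        return self.total_flops + self.deform_interp_flops

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.rows])

    def summary(self) -> str:
        return (f"params: {self.total_params / 1e6:.1f}M  "
                f"flops: {self.total_flops / 1e9:.1f}G "
                f"(+{self.deform_interp_flops / 1e9:.2f}G deformable interpolation)")


def _resolve_spec(spec) -> NetworkSpec:
    if isinstance(spec, EYOLONet):
        return spec.spec()
    if isinstance(spec, NetworkSpec):
        return spec
    raise TypeError(f"cannot profile object of type {type(spec)!r}")


def _rows_for(layer: LayerDef, input_size: tuple[int, int]) -> list[ProfileRow]:
    h, w = input_size
    h_out, w_out = h // layer.out_stride, w // layer.out_stride
    rows = [ProfileRow(
        layer.name, layer.c_in, layer.c_out, layer.kh, layer.kw, h_out, w_out,
        layer_flops(layer.c_in, layer.c_out, layer.kh, layer.kw, h_out, w_out),
        conv_params(layer.c_in, layer.c_out, layer.kh, layer.kw,
                    bias=layer.has_bias, bn=layer.has_bn))]
    if layer.deformable:
        # parallel plain 3x3 convolution predicting 2 offsets per base offset
        off_out = 2 * layer.kh * layer.kw
        rows.append(ProfileRow(
            layer.name + ".offset", layer.c_in, off_out, 3, 3, h_out, w_out,
            layer_flops(layer.c_in, off_out, 3, 3, h_out, w_out),
            conv_params(layer.c_in, off_out, 3, 3, bias=True, bn=False)))
    return rows


def count_flops(spec, input_size: int | tuple[int, int] = 256) -> ModelProfile:
    """Eq-14 FLOPs (and params) of every convolution layer in the spec."""
    net_spec = _resolve_spec(spec)
    if isinstance(input_size, int):
        input_size = (input_size, input_size)
    rows: list[ProfileRow] = []
    interp = 0
    for layer in net_spec.layers:
        rows.extend(_rows_for(layer, input_size))
        if layer.deformable:
            h_out = input_size[0] // layer.out_stride
            w_out = input_size[1] // layer.out_stride
            interp += 4 * (layer.kh * layer.kw) * h_out * w_out * layer.c_in
    return ModelProfile(
        rows=rows,
        total_params=sum(r.params for r in rows),
        total_flops=sum(r.flops for r in rows),
        deform_interp_flops=interp,
    )


def count_params(spec) -> ModelProfile:
    """Trainable-parameter count (spatial size does not matter)."""
    return count_flops(spec, input_size=(32, 32))


def profile_table(spec, input_size: int | tuple[int, int] = 256) -> pd.DataFrame:
    return count_flops(spec, input_size).to_dataframe()
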