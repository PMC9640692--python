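"""Build model instances by short name."""

from __future__ import annotations

from dataclasses import replace

from ..params import AITParams, CoupledParams, NoiseParams, SwitchParams
from .ait import AITModel
from .coupled import CoupledModel
from .switch import SwitchModel

MODEL_NAMES = ("ait", "ait_seqa", "ld", "lddr", "coupled")


def make_model(name: str, params=None, noise: NoiseParams | None = None, **kw):
    """Construct a model family by name.

    ``params`` may be a ready parameter object; otherwise defaults for the
    family are used.  Extra keyword arguments are forwarded to the model
    constructor (e.g. ``init_l`` for perturbation runs).
    """
    if name == "ait":
        p = params if params is not None else AITParams(seqa_mode="origin_block_only")
        if p.seqa_mode == "synthesis_block":
            raise ValueError("model 'ait' must not use the synthesis block; use 'ait_seqa'")
        return AITModel(p, noise=noise, **kw)
    if name == "ait_seqa":
        p = params if params is not None else AITParams(seqa_mode="synthesis_block")
        if p.seqa_mode != "synthesis_block":
            p = replace(p, seqa_mode="synthesis_block")
        return AITModel(p, noise=noise, **kw)
    if name == "ld":
        p = params if params is not None else SwitchParams.ld()
        return SwitchModel(p, noise=noise, name="ld", **kw)
    if name == "lddr":
        p = params if params is not None else SwitchParams()
        return SwitchModel(p, noise=noise, name="lddr", **kw)
    if name == "coupled":
        p = params if params is not None else CoupledParams()
        return CoupledModel(p, noise=noise, **kw)
    raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")
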