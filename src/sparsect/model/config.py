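"""Architecture configuration for the residual dual-frame U-Net."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class UNetConfig:
    """Configurable dual-frame U-Net.

    The default (``UNetConfig.paper()``) instantiates the published
    architecture: four encoder blocks of paired 3x3 conv + batch norm +
    ReLU with channel widths 64/128/256/512, 2x2 max pooling, a bottleneck
    (512 -> 1024 -> 512), four decoder blocks with 2x2 nearest-neighbor
    upsampling, concatenating skip connections and channel widths mirroring
    the encoder (second decoder conv halves the width), parameter-free
    additive dual-frame bridges from each pooled encoder output to the
    associated decoder input before upsampling, and a final 1x1 conv.

    Counting convention pinned by the published total of 21,971,584:
    convolutions carry no bias terms and batch norm carries no learned
    affine parameters, so the count is exactly the kernel weights.
    """

    input_size: int = 512
    in_channels: int = 1
    depth: int = 4
    base_channels: int = 64
    kernel_size: int = 3
    dual_frame: bool = True
    conv_bias: bool = False
    bn_affine: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be positive")
        if self.input_size % (2**self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 2^depth = {2 ** self.depth}"
            )

    @classmethod
    def paper(cls) -> "UNetConfig":
        """The published 512 x 512 configuration (21,971,584 parameters)."""
        return cls()

    @classmethod
    def toy(cls, input_size: int = 64, depth: int = 2, base_channels: int = 8, seed: int = 0) -> "UNetConfig":
        """A small CPU-friendly configuration for desk-scale experiments."""
        return cls(input_size=input_size, depth=depth, base_channels=base_channels, seed=seed)

    @property
    def encoder_channels(self) -> tuple[int, ...]:
        return tuple(self.base_channels * 2**i for i in range(self.depth))

    @property
    def bottleneck_channels(self) -> int:
        return self.base_channels * 2**self.depth
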