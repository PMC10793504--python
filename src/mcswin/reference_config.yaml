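# Frozen reference configuration of the multi-channel Swin encoder-decoder.
# Building this config yields exactly 4,990,032 trainable parameters.
attention_scale: per_head_sqrt
decoder_depths: null
embed_bias: true
embed_norm: true
filters_per_channel: 12
heads_per_stage: [3, 6, 12]
in_channels: 8
input_size: 48
mlp_ratio: 4.0
num_classes: 11
patch_size: 4
qkv_bias: true
shift_size: null
stage_depths: [2, 2, 1]
use_relative_position_bias: true
window_size: 6
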