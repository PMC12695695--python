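"""Score a CBCT against its ground-truth CT with the masked image metrics.

Preprocessing (HU clipping to [-1024, 3072]) is applied first; all metrics
are evaluated over the head only, never the background.  The CBCT's own
scores are the baseline any synthetic CT must beat.
"""

from dualsct import metrics, phantom, proton, volio

triplet = phantom.generate_triplet(phantom.PhantomSpec(seed=11))
ct = volio.clip_hu(triplet.ct)
cbct = volio.clip_hu(triplet.cbct)
head = metrics.RegionMask(triplet.labels.head_mask(), "whole_head")

mae = metrics.masked_mae(cbct, ct, head)
psnr = metrics.masked_psnr(cbct, ct, head)
ssim = metrics.masked_ssim(cbct, ct, head)
spr_re, _ = proton.spr_relative_error(cbct, ct, mask=head)

print(f"CBCT vs CT over {head.n_voxels} head voxels")
print(f"  MAE   {mae:7.1f} HU   (mean absolute HU error)")
print(f"  PSNR  {psnr:7.2f} dB   (10 log10(4096^2 / MSE))")
print(f"  SSIM  {ssim:7.3f}      (3D structural similarity, 7^3 windows)")
print(f"  SPR RE{spr_re:7.2f} %    (mean relative stopping-power error)")
print("\nA synthetic CT is useful when its MAE / SPR RE drop well below "
      "these CBCT values while SSIM and PSNR rise.")
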