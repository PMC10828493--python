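"""The five-stage filter chain on a noisy phantom.

Applies Gaussian -> median -> mean -> bilateral -> sharpening with hand-set
parameters and reports how far the result moved back toward the clean image.
"""

from chaoswidow import (
    FilterChainParams,
    NoiseSpec,
    PhantomSpec,
    add_noise,
    apply_chain,
    make_phantom,
    psnr,
)

ref = make_phantom(PhantomSpec(kind="piecewise_constant", size=128))
noisy = add_noise(ref, NoiseSpec(kind="salt_pepper", sp_density=0.05, seed=1))

params = FilterChainParams(
    gaussian_sigma=0.7, gaussian_ksize=3,
    median_ksize=5, mean_ksize=3,
    bilateral_sigma_r=30.0, bilateral_sigma_d=2.0, bilateral_ksize=5,
    sharpen_amount=0.3,
)
denoised = apply_chain(noisy, params)

print(f"PSNR noisy    : {psnr(ref, noisy):6.2f} dB")
print(f"PSNR denoised : {psnr(ref, denoised):6.2f} dB")
print("\nThe median stage removes the salt-and-pepper impulses; the gain in "
      "PSNR is the decibel reduction in mean squared error vs the clean image.")
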