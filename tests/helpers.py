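import numpy as np

from mmtissue.images import MultichannelImage


def pca_compress(img: MultichannelImage, n_components: int = 3) -> MultichannelImage:
    """Reduce an image's channels to a few principal components — stands in
    for the pixel-embedding compression stage in registration tests."""
    from sklearn.decomposition import PCA

    h, w, c = img.data.shape
    X = img.data.reshape(-1, c).astype(float)
    Z = PCA(n_components=n_components, svd_solver="full").fit_transform(X)
    return MultichannelImage(
        Z.reshape(h, w, -1).astype(np.float32),
        [f"pc{i}" for i in range(Z.shape[1])],
    )
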