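>tau187 human 4R tau residues 255-441, C291S
NVKSKIGSTENLKHQPGGGKVQIINKKLDLSNVQSKSGSKDNIKHVPGGGSVQIVYKPVD
LSKVTSKCGSLGNIHHKPGGGQVEVKSEKLDFKDRVQSKIGSLDNITHVPGGGNKKIETH
KLTFRENAKAKTDHGAEIVYKSPVVSGDTSPRHLSNVSSTGSIDMVDSPQLATLADEVSA
SLAKQGL
>tau187his tau187 with N-terminal expression tag
MGSSHHHHHHSSGLVPRGSHNVKSKIGSTENLKHQPGGGKVQIINKKLDLSNVQSKSGSK
DNIKHVPGGGSVQIVYKPVDLSKVTSKCGSLGNIHHKPGGGQVEVKSEKLDFKDRVQSKI
GSLDNITHVPGGGNKKIETHKLTFRENAKAKTDHGAEIVYKSPVVSGDTSPRHLSNVSST
GSIDMVDSPQLATLADEVSASLAKQGL
>tau114 human 4R tau residues 255-368, C291S
NVKSKIGSTENLKHQPGGGKVQIINKKLDLSNVQSKSGSKDNIKHVPGGGSVQIVYKPVD
LSKVTSKCGSLGNIHHKPGGGQVEVKSEKLDFKDRVQSKIGSLDNITHVPGGGN
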