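>EcoRI_M1-K277 reconstructed by stitching the overlapping blocking-peptide set; synthetic reference, not a database record
MSNKKQSNRLTEQHKLSQGVIGIFGDYAKAHDLAVGEVSKLVKKALSNEYPQLAFRYRDS
IKKTEINEALKKIDPDLGGTLFVSNSSIKPDGGIVEVKDDYGEWRVVLVAEAKHQGKDII
NIRNGLLVGKRGDQDLMAAGNAIERSHKNISEIANFMLSESHFPYVLFLEGSNFLTENIS
ITRPDGRVVNLEYNSGILNRLDRLTAANYGMPINSNLCINKFVNHKDKSIMLQAASIYTQ
GDGREWDSKIMFEIMFDISTTSLRVLGRDLFEQLTSK
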