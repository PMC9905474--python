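# Anti-neoplastic agent -> therapy class. Classes recognised downstream:
# chemotherapy, PD-1, PD-L1, CTLA4, oncogene TKI, hormonal, other.
pembrolizumab: PD-1
nivolumab: PD-1
cemiplimab: PD-1
atezolizumab: PD-L1
durvalumab: PD-L1
avelumab: PD-L1
ipilimumab: CTLA4
carboplatin: chemotherapy
cisplatin: chemotherapy
pemetrexed: chemotherapy
paclitaxel: chemotherapy
docetaxel: chemotherapy
gemcitabine: chemotherapy
capecitabine: chemotherapy
fluorouracil: chemotherapy
erlotinib: oncogene TKI
osimertinib: oncogene TKI
alectinib: oncogene TKI
letrozole: hormonal
anastrozole: hormonal
tamoxifen: hormonal
leuprolide: hormonal
bevacizumab: other
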