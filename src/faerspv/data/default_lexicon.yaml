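# Default drug lexicon and analysis vocabularies.
# Category membership is decided by exact match on normalized names
# (trimmed, whitespace-collapsed, case-folded), never by substring.

index_synonyms:
  - Bevacizumab
  - Avastin

# Reports naming only a biosimilar form of the index drug are excluded.
biosimilar_denylist:
  names:
    - Mvasi
    - Zirabev
    - Alymsys
    - Vegzelma
    - Avzivi
  prefixes:
    - bevacizumab-

chemotherapy:
  # platinum drugs
  - Cisplatin
  - Carboplatin
  - Paraplatin
  - Nedaplatin
  - Oxaliplatin
  # pemetrexed
  - Pemetrexed
  - Alimta
  # gemcitabine
  - Gemcitabine
  - Gemzar
  # taxoid drugs
  - Paclitaxel
  - Taxol
  - Albumin-bound paclitaxel
  - Nab-paclitaxel
  - Abraxane
  - Docetaxel
  - Taxotere
  - Anzatax
  # vinca alkaloids
  - Vindesine
  - Vinorelbine
  - Navelbine
  # etoposide
  - Etoposide
  - VP-16
  # other drugs
  - Irinotecan
  - Topotecan
  - Mitomycin
  - Amrubicin
  - Ifosfamide
  - Cyclophosphamide
  - Bortezomib
  - Everolimus
  - Temozolomide
  - Thalomid
  - Capecitabine
  - Fluorouracil
  - 5-FU

ici:
  # anti-PD-1
  - Nivolumab
  - Pembrolizumab
  - Cemiplimab
  - Opdivo
  - Keytruda
  - Libtayo
  # anti-PD-L1
  - Atezolizumab
  - Durvalumab
  - Avelumab
  - Imfinzi
  - Bavencio
  - Tecentriq
  # anti-CTLA-4
  - Ipilimumab
  - Tremelimumab
  - Yervoy

targeted:
  # EGFR-TKI
  - Iressa
  - Gefitinib
  - Tarceva
  - Erlotinib
  - Gilotrif
  - Afatinib
  - Tagrisso
  - Osimertinib
  - Dacomitinib
  - Vizimpro
  - Lapatinib
  - Tykerb
  - Icotinib
  - Conmana
  # EGFR antibody
  - Cetuximab
  - Erbitux
  # ALK-TKI
  - Crizotinib
  - Xalkori
  - Alectinib
  - Alecensa
  - Ceritinib
  - Zykadia
  - Entrectinib
  - Rozlytrek
  - Brigatinib
  - Alunbrig
  - Lorlatinib
  - Lorviqua
  # other drugs
  - Cediranib
  - Temsirolimus
  - CCI-779
  - Endostatin
  - Sorafenib
  - Herceptin
  - Trastuzumab
  - Rituxan
  - Rituximab
  - Trebananib
  - AMG 386
  - Faslodex
  - Lucentis

target_pts:
  - Pulmonary haemorrhage
  - Haemoptysis

# Indication preferred terms are mapped onto summary categories by
# case-insensitive keyword containment, first matching category wins.
indication_categories:
  Lung cancer: [lung, nsclc, non-small cell, small cell, bronch]
  Colorectal cancer: [colorect, colon, rectal, rectum]
  Breast cancer: [breast]
  Renal cancer: [renal, kidney]
  Gastric cancer: [gastric, stomach]
  Head and neck cancer: [head and neck, nasopharyn, oropharyn, laryn]
  Ovarian cancer: [ovar]
  Uterus cancer: [uter, cervi, endometri]
  Liver cancer: [liver, hepatocell, hepatic]

# Countries reported individually; everything else lands in Others.
countries:
  United States: [us, usa, united states, united states of america]
  Japan: [jp, japan]
  China: [cn, china]
  United Kingdom: [gb, uk, united kingdom, great britain]
  Germany: [de, germany]
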