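>Otauri_CK1_synthetic synthetic CK1 kinase-domain stand-in
TDDSSDGPVEDPHRGYMKTHKHWTCDEFTQAISQFQHRFLRTAWKAQMMDVHNKVVNACC
SMNLLSPDVIQASGREKSLQCAVVEKTRDKYMKDFIEKTQWWWFWSIFHLVHTFEKLMPK
DKIDVGNYAHDIRVRLRITDIVDFTEGCPVVKCRLHNRTVPMHELMRAWANDQIVTIWNH
TMQGKLQDQSSAWDNKKFARRIMWNHERRAGNTMFIEEPDMKHWHARVDRPPLMEMFIER
FWCTFATDVKHQDRYREDRF
>Hsapiens_CK1d_synthetic synthetic CK1 kinase-domain stand-in
TDDSSDCGVEDPHRGSMTTHETQTCDEFTQACSQFQHRFLRTA-KAQMMDMHNKVVNRCC
VMTQLSPDVIQASWREKSLQCAVVEKTRDKYMVDFIEKTQWWWFWSIFMLVHTFE-LMPK
DKI-VGNYAHLIRVRSRITDIVDFTETEPVVKCRLHNRTPPMHELMRAWQNDQIVTIWNH
TMQNQLQDQSSAWDNKKFARRIMWNHERRAGNTMFILEPDMKHWMARVDRPPLMEMFIER
FWCTF-IKVKHQDRYREDRF
>Hsapiens_CK1e_synthetic synthetic CK1 kinase-domain stand-in
TDDPSDGKVEDPHIGYMKDHLHWTDDETTQFIWQ-QHRFLRTAWKAQM-DVHVSVVNACC
SMPLLSPDVIQASGTEKSHQCAVVEKTRDKTMKDFIEKTQWWWFWSAFMLVHTFEKLMPK
DKIDEGNYAHDIRKRLRITDIVDFTWGMPVVKC-LH-RTVPMHELMRAWANDWIVTIWNH
TMQGKLQDQSSAWDNKKFARRIMWNHERRAGNTMFIEDPDMKHWHAHVDHPPLMEMFIER
FWCDFATDVKHQDRYREDAF
>Mmusculus_CK1e_synthetic synthetic CK1 kinase-domain stand-in
TDNSKDGPVEDPHRGYMKTHKHWTIDEFTQAISQFQHRFLRTAWDRQMMDVHNKVVNACC
SMNLLSPLVI-ASGREKSLQCTVVEKTRDKAMKDFIEKTQWWFFWSIAHLVHTFSKLMPK
DKIDVGNYNHDLRVRLRITDIVDFTEGCPVVKCRLHNEPSPMHELMRAVANYQ-VTIWNR
WMQQKLQDQSSAWDNKKFARRIMWNHERRAGNTMF-EEPDMRHRHAR-DRPPLMEMFGER
FWCTNATDAKHQ-RYRVDRF
>Mauratus_CK1e_synthetic synthetic CK1 kinase-domain stand-in
TDDSSFG-VMDPLRGYMKTHKHWTCDEFTQAISQFQHRFLRTACKAQMMDVHNKVVDAAC
-M-LLSPYVIQAVGREKSLQCAVVEKTRDKYMKDFIEHTQWWWFWPISHLVHTFEKCMPK
G-IDDGNYAHDWRKRLRRTDIVDFTEGCPVVKCRLHNRTVP-HELCRKWANDQIVTIWNH
TMQGKNQDQSSAWDNKKFARRIMWNHERRAGNTMFIEEPDMKEWHARVDRPPLMEM-IER
FWCEFAQDVKHQDRYREDRF
>Dmelanogaster_DBT_synthetic synthetic CK1 kinase-domain stand-in
TDDSSDGPVEDPHRGYMKDHK-WTCDDFTQAISQNQMQALEPAWKAQMMDHHNKVVNAMC
SGNLLSPDVIQASH-EKSLQCAVVEKTRDKYMKNDIWKTQ-QWFWSIFHLIHTFEKLMPK
DKIDPGFYAHD-RVRLRITDIVDFTEGCPVVKCRLHNETVPMHELMADWANDQIVTIWNH
IMQIKLQSQSSAWDNKKFARRIMWNHERRAGNTKFIEEMDMKLWHARVDRPPLMEDFIER
FWCTFATDVKHQDRYR-DRF
>Ncrassa_CK1a_synthetic synthetic CK1 kinase-domain stand-in
TDDSSDFPVEDPQRGYMKKHKEWTCDECTQAISQFQHRFLRTATKADMMDVHNFVVNACC
SMNLLCPDVIQASGRTKSKQCADVEK-RDKYMKDFIEKTQ-WWFWSIDHLVHTFEKLMP-
FKIDVGNYAHGIRVRLPITDQKDFTEGCPVVKCGLHNETVPMHELMRFWANDQIVTIWNH
TMQGKLFDQSSAWDNKKFARRIMWNHERRAGNTMCQEEPDMKHWHARVDHPPLYEMFIER
FWCTFATDVKYQDRYREDRF
>Athaliana_CKL_synthetic synthetic CK1 kinase-domain stand-in
TDHSSDGPVEDPHRVYMKTHKRWTCDEF-QAISQFQHHFLRTAWKAQMMQVHNKVVNACC
SMNLLSPDVIQHSGREKS-QCAQVLKLRDNYMWDFIEKTQWWTFWSIFHLVHTFEK-MVK
DKITVGNYAHDFGVRLRITLIVDFYFGCPVVKCRLHNRTEQQTELMRAFANDQINTSWNH
TMQGRLQDQSSAWDNKKFARRIMWNHERRAGNTMFIEEPDMKHWHARNYNPPLMEHFPER
FWCTFATDVKHQVRYREDRF
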