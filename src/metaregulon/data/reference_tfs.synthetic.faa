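>FNR_ref synthetic stand-in playing the E. coli FNR reference role
MYSKEHVHKFSAELRAHFECNHCKTTGVCGQQPFVHPLGVLAGFFQTYSATHGMLHLLRWPQVRWGERKV
GNWQGHTLQLWGSHNHKWEVQDVEMDELYIGSDCHRNWMIKLVSKNPAGRMCYAHMWRAEDGIFLIEPAS
SFGHLMVITVDNSRHTPYHMWFAEIPEIWWYWEGNKRLNAWMKWIFWGMHASSYNPMHRALWWLPWVRTP
TRKRMKHMIEGLDPIVPKGCEGEDRNVNFK
>DNR_ref synthetic stand-in playing the P. aeruginosa PAO1 DNR reference role
IMSFFWQLVKITQDRTHDPSGFYMRVEESSAGAGFWPMFVFYPMFWGMRGTETLRYCILPHFLSMFTQDN
GKYRYYKVWITRDSGTYHSVMSFAFPTDQVEAVIMWKTISYTKRWTEIYVRMLRLHSKDHDDDGFQLEHP
IMRAVPQYHDWTNETEPIGIYVSVDIGPRGWMHRVSATALWAACRHRQPMRLPVGESPPPHRNGWEPVAW
NQHNGTKHIGYPFRDQPIMMIASLETGNID
>NnrR_ref synthetic stand-in playing the R. sphaeroides NnrR reference role
RNDQVHYLQEHGYRYNEAGALFWIIFNWYQSVMQTHWIYWPQKYDWCFWNYWWIQRIRISAAFDAQEYSQ
KSQHWQQPVRYYTKIGYIYRKNYAGLGWFPGGSPMPMNQLNLHIFIIIPIGSVHIHYEYKKFRSVMGRLW
QDRSDFIFLAALLEFSLSNHIEFSHDSLIARTDAMTTRDPCAGFGGDKTQENIFDPRGAVDKHPVSIISN
RSPWANFMDPKEVPEQIWEMHMQLMRIGYA
>CRP_ref synthetic stand-in playing the E. coli CRP reference role
FANGDEMFHQTAHLKDREKRVWTKRQMDPNIPGYELQFIQRLGTNMIWMNQFADHKNILGQWGAQDTESN
AQDKMKELGGFLDILANPLINYVYVFCNWADWGMKTHLKLAYGLPSNNQDISSPQMDQFAYRLAYEFQKH
LETEAWLNHQAWLFYEAVNNNANGIYANMWHKAAHQMIIEWPHYFGHVPRHDSDQFHPLPHKAYIQQDSD
TPQFDEKRDMFMLEKHSVMDCPWEWLAIEM
>MalR_ref synthetic stand-in playing the B. thetaiotaomicron MalR reference role (effector-binding domain 120-220)
RMMFEQAPFCFVIDFEVFWRFPVNQIENPIADTVMFQAQFFMYHKPQATAATYFHCRDKNGMDIFLQQPW
REDPVHWPHFQVSSVQFDYFTNIGRPFGAQGSQSSKAAPNIPDQVDWQANFRTAPQTWYTFDPTNMVRRD
GPALNVGVMQENLNSGTSQRWMQTFDESDVTMWRNFIIYNQNPQAGLEEFPSIGHQWNWWEPSYVDTKEP
HRDREWTHNSEGPMVRWFYARPETAGMVEK
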